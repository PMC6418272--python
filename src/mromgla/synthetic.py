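"""Synthetic stand-ins for a monosyllabic lexicon and region-signal tables.

The lexicon generator emulates the statistical shape of a monosyllabic
3-5-letter lexicon: consonant/vowel skeleton templates (CVC, CVCC, CCVC,
CCVCC, CVCCC) over a restricted consonant inventory, with Zipf-distributed
token frequencies. The restricted inventory is what produces realistic
orthographic neighborhood overlap — the single property downstream stages
consume. No phonotactic grammar is attempted.

The region-signal generator produces balanced subject x lexicality x
GLA-level tables of scalar signal change with additive Gaussian subject
random effects, programmable per-level linear slopes that may differ
between words and nonwords, and homoscedastic within-cell noise:

    value(s, l, j) = grand_mean + b_s + slope_l * j + eps,
    b_s ~ N(0, subject_sd^2),  eps ~ N(0, residual_sd^2),  j in {0,1,2}.

Both generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .lexicon import Lexicon
from .network import ModelParams

__all__ = [
    "LexiconSpec",
    "SignalSpec",
    "generate_synthetic_lexicon",
    "generate_region_signals",
    "micro_fixture",
    "LEVELS",
]

LEVELS: tuple[str, str, str] = ("low", "medium", "high")

_CONSONANTS = "bdfghklmnprst"
_VOWELS = "aeiou"
_TEMPLATES: Mapping[int, tuple[str, ...]] = MappingProxyType(
    {3: ("CVC",), 4: ("CVCC", "CCVC"), 5: ("CCVCC", "CVCCC")}
)


@dataclass(frozen=True)
class LexiconSpec:
    """Parameters of the synthetic lexicon.

    Defaults emulate a lexicon of 1025 monosyllabic 3-5-letter words with
    a little over half of the entries four letters long.
    """

    n_words: int = 1025
    length_distribution: tuple[tuple[int, float], ...] = ((3, 0.25), (4, 0.54), (5, 0.21))
    consonants: str = _CONSONANTS
    vowels: str = _VOWELS
    zipf_exponent: float = 1.05
    freq_max: float = 2000.0
    seed: int = 0
    min_neighbor_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words >= 1")
        total = sum(p for _, p in self.length_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length proportions must sum to 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent >= 0")
        if set(self.consonants) & set(self.vowels):
            raise ValueError("consonant/vowel sets must be disjoint")


def _template_capacity(spec: LexiconSpec, length: int) -> int:
    nc, nv = len(spec.consonants), len(spec.vowels)
    cap = 0
    for tpl in _TEMPLATES[length]:
        n = 1
        for slot in tpl:
            n *= nc if slot == "C" else nv
        cap += n
    return cap


def _length_counts(spec: LexiconSpec) -> dict[int, int]:
    lengths = [l for l, _ in spec.length_distribution]
    props = np.array([p for _, p in spec.length_distribution])
    counts = np.floor(props * spec.n_words).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    remainder = spec.n_words - counts.sum()
    frac = props * spec.n_words - counts
    for i in np.argsort(-frac)[:remainder]:
        counts[i] += 1
    return dict(zip(lengths, counts.tolist()))


def _sample_words(spec: LexiconSpec, rng: np.random.Generator) -> list[str]:
    counts = _length_counts(spec)
    cons = list(spec.consonants)
    vows = list(spec.vowels)
    words: list[str] = []
    seen: set[str] = set()
    for length, need in counts.items():
        if need == 0:
            continue
        cap = _template_capacity(spec, length)
        if need > 0.8 * cap:
            raise ValueError(
                f"{need} words of length {length} exceed 80% of the "
                f"template space ({cap}); enlarge the alphabet"
            )
        templates = _TEMPLATES[length]
        got = 0
        while got < need:
            tpl = templates[int(rng.integers(len(templates)))]
            w = "".join(
                cons[int(rng.integers(len(cons)))] if slot == "C"
                else vows[int(rng.integers(len(vows)))]
                for slot in tpl
            )
            if w not in seen:
                seen.add(w)
                words.append(w)
                got += 1
    return words


def _neighbor_fraction(words: list[str], length: int) -> float:
    """Fraction of words of *length* with at least one substitution neighbor."""
    pool = [w for w in words if len(w) == length]
    if not pool:
        return 1.0
    wset = set(pool)
    alphabet = sorted({c for w in pool for c in w})
    have = 0
    for w in pool:
        found = False
        for i in range(length):
            for c in alphabet:
                if c != w[i] and w[:i] + c + w[i + 1 :] in wset:
                    found = True
                    break
            if found:
                break
        if found:
            have += 1
    return have / len(pool)


def generate_synthetic_lexicon(spec: LexiconSpec | None = None) -> Lexicon:
    """Generate a deterministic synthetic lexicon from *spec*.

    Zipf frequencies: the word of rank r gets ``freq_max * r**(-s)`` per
    million (rank 1 = ``freq_max``); ranks are assigned by a seeded
    permutation so frequency is independent of string structure. If fewer
    than ``min_neighbor_fraction`` of the four-letter words have a
    substitution neighbor the draw is repeated with a fresh sub-seed.
    """
    spec = spec or LexiconSpec()
    for attempt in range(32):
        rng = np.random.default_rng((spec.seed, attempt))
        words = _sample_words(spec, rng)
        if _neighbor_fraction(words, 4) >= spec.min_neighbor_fraction:
            break
    else:  # pragma: no cover - only reachable with pathological specs
        raise RuntimeError("could not realize the requested neighborhood density")

    ranks = np.empty(len(words), dtype=int)
    ranks[rng.permutation(len(words))] = np.arange(1, len(words) + 1)
    freqs = spec.freq_max * ranks.astype(float) ** (-spec.zipf_exponent)
    lengths = sorted({l for l, _ in spec.length_distribution})
    return Lexicon.from_entries(
        zip(words, freqs),
        alphabet=spec.consonants + spec.vowels,
        length_bounds=(lengths[0], lengths[-1]),
    )


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the synthetic region-signal generator.

    Slopes are per level step (levels coded 0, 1, 2), in the same
    arbitrary signal-change units as ``grand_mean`` and the noise sds.
    """

    n_subjects: int = 20
    word_slope: float = 0.0
    nonword_slope: float = 0.0
    grand_mean: float = 0.2
    subject_sd: float = 0.1
    residual_sd: float = 0.1
    seed: int = 0
    region: str = "region"

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects >= 3")
        if self.subject_sd < 0 or self.residual_sd < 0:
            raise ValueError("sds must be >= 0")


def generate_region_signals(spec: SignalSpec | None = None) -> pd.DataFrame:
    """Balanced long-format table `region, subject, lexicality, level, value`."""
    spec = spec or SignalSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    b = rng.normal(0.0, spec.subject_sd, size=n)
    eps = rng.normal(0.0, spec.residual_sd, size=(n, 2, 3))
    slopes = {"word": spec.word_slope, "nonword": spec.nonword_slope}
    rows = []
    for s in range(n):
        for li, lex in enumerate(("word", "nonword")):
            for j, level in enumerate(LEVELS):
                rows.append(
                    {
                        "region": spec.region,
                        "subject": f"s{s + 1:02d}",
                        "lexicality": lex,
                        "level": level,
                        "value": spec.grand_mean + b[s] + slopes[lex] * j + eps[s, li, j],
                    }
                )
    return pd.DataFrame(rows)


def micro_fixture() -> tuple[Lexicon, list[tuple[str, str]], ModelParams]:
    """Fixed 8-word toy lexicon, 4 stimuli and frozen parameters.

    The stimuli are two words (one from a dense neighborhood, one sparse)
    and two nonwords (one with three word neighbors, one with none), so
    oracle tests cover the full range of lexical overlap. Parameter values
    are written out literally so the fixture never drifts with defaults.
    """
    lexicon = Lexicon.from_entries(
        [
            ("lamp", 120.0),
            ("lamb", 8.0),
            ("land", 95.0),
            ("lane", 30.0),
            ("damp", 12.0),
            ("ramp", 6.0),
            ("desk", 40.0),
            ("dusk", 4.0),
        ],
        alphabet="abdegklmnoprstu",
        length_bounds=(3, 5),
    )
    stimuli = [
        ("lamp", "word"),      # dense neighborhood word
        ("desk", "word"),      # sparse neighborhood word
        ("lanp", "nonword"),   # neighbors: lamp, land, lane
        ("gost", "nonword"),   # no neighbors
    ]
    params = ModelParams(
        excite_letter_word=0.07,
        inhibit_letter_word=0.04,
        inhibit_word_word=0.10,
        feedback_word_letter=0.30,
        decay=0.07,
        a_max=1.0,
        a_min=-0.2,
        rest_range=(-0.92, 0.0),
        input_clamp=1.0,
        gla_cycles=7,
        m_criterion=0.55,
        s_base=1.1,
        s_gain=1.5,
        s_min=0.4,
        t_base=20,
        t_gain=10.0,
        adjust_cycle=3,
    )
    return lexicon, stimuli, params
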