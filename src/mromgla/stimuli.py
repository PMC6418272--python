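"""Stimulus construction: nonword pool, constrained selection, leveling.

Mirrors the construction of a GLA-graded stimulus set:

1. Generate a nonword pool from the four-letter words by substituting
   1-4 letters, excluding anything that is itself a word.
2. Compute each candidate's global lexical activity (GLA) in the
   interactive-activation network and z-score it over the joint pool.
3. Select n words and n nonwords whose z-GLA distributions are normal
   (Shapiro-Wilk), have significantly different means (Welch t) and
   equal variances (Levene, median-centered).
4. Split each selected class into low/medium/high GLA tertiles and
   tabulate per-level means of the psycholinguistic measures.

Selection is deterministic given the seed. The proposal step matches the
candidates to the order statistics of two normal distributions with a
common sd and separated means; a rejection/trimming loop then re-tests
and, on failure, drops extreme-tail candidates and re-proposes. The
three statistical constraints are always re-audited on the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import Lexicon, OrthoMeasures, ortho_measures
from .network import InteractiveActivationModel, ModelParams, z_transform
from .synthetic import LEVELS

__all__ = [
    "StimulusRecord",
    "SelectionConstraints",
    "SelectionError",
    "generate_nonword_pool",
    "select_stimuli",
    "assign_gla_levels",
    "descriptor_table",
    "gla_correlations",
    "build_stimulus_set",
    "stimulus_frame",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = [
    "word", "lexicality", "GLA", "GLAz", "level",
    "LogF", "Fmio", "N", "FN", "NHF", "FHN", "BiC", "BiF", "BiN",
]

_CORR_MEASURES = ["N", "FN", "NHF", "FHN", "BiC", "BiF", "BiN"]


class SelectionError(RuntimeError):
    """Selection constraints unsatisfiable within the iteration budget."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class StimulusRecord:
    """One word or nonword with its GLA and orthographic measures."""

    string: str
    lexicality: str
    gla_raw: float
    gla_z: float
    level: str | None = None
    measures: OrthoMeasures | None = None

    def __post_init__(self) -> None:
        if self.lexicality not in ("word", "nonword"):
            raise ValueError(f"lexicality must be word|nonword, got {self.lexicality!r}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


@dataclass(frozen=True)
class SelectionConstraints:
    """Statistical constraints the two selected z-GLA samples must satisfy."""

    n_per_class: int = 300
    normality_alpha: float = 0.10
    mean_diff_alpha: float = 0.01
    variance_alpha: float = 0.10
    max_iterations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("normality_alpha", "mean_diff_alpha", "variance_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_per_class < 3:
            raise ValueError("n_per_class >= 3")


def generate_nonword_pool(
    words: Sequence[str],
    lexicon: Lexicon,
    n_pool: int,
    seed: int,
    max_substitutions: int = 4,
) -> list[str]:
    """Nonwords derived from *words* by substituting 1..4 letters.

    Each candidate substitutes k (uniform on 1..max_substitutions)
    distinct positions of a uniformly chosen source word with uniformly
    chosen different letters from the lexicon's alphabet. Candidates that
    are lexicon words, or duplicates, are rejected and redrawn.
    """
    if n_pool == 0:
        return []
    if not words:
        raise ValueError("no source words")
    lengths = {len(w) for w in words}
    if len(lengths) != 1:
        raise ValueError("source words must all have the same length")
    length = lengths.pop()
    alphabet = sorted(lexicon.alphabet)
    if len(alphabet) < 2:
        raise ValueError("alphabet too small for letter substitution")
    max_substitutions = min(max_substitutions, length)

    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    budget = 200 * n_pool
    tries = 0
    while len(out) < n_pool:
        tries += 1
        if tries > budget:
            raise SelectionError(
                f"nonword pool of {n_pool} unreachable within {budget} draws "
                f"({len(out)} found)"
            )
        source = words[int(rng.integers(len(words)))]
        k = int(rng.integers(1, max_substitutions + 1))
        positions = rng.choice(length, size=k, replace=False)
        chars = list(source)
        for p in positions:
            options = [c for c in alphabet if c != chars[p]]
            chars[p] = options[int(rng.integers(len(options)))]
        cand = "".join(chars)
        if cand in lexicon or cand in seen:
            continue
        seen.add(cand)
        out.append(cand)
    return out


def _audit(
    wz: np.ndarray, nz: np.ndarray, c: SelectionConstraints
) -> tuple[bool, dict[str, float]]:
    """Run the three selection tests; return (all pass, p-values)."""
    sh_w = stats.shapiro(wz).pvalue
    sh_n = stats.shapiro(nz).pvalue
    welch = stats.ttest_ind(wz, nz, equal_var=False).pvalue
    levene = stats.levene(wz, nz, center="median").pvalue
    ok = (
        sh_w > c.normality_alpha
        and sh_n > c.normality_alpha
        and welch < c.mean_diff_alpha
        and levene > c.variance_alpha
    )
    return ok, {
        "shapiro_words": sh_w,
        "shapiro_nonwords": sh_n,
        "welch": welch,
        "levene": levene,
    }


def _match_quantiles(values: np.ndarray, avail: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Indices of available candidates nearest (monotonically) to sorted targets."""
    idx = avail[np.argsort(values[avail], kind="stable")]
    v = values[idx]
    m, n = len(idx), len(targets)
    picks = np.empty(n, dtype=int)
    j = 0
    for i, q in enumerate(targets):
        jmax = m - (n - i)  # leave enough candidates for the remaining targets
        while j < jmax and abs(v[j + 1] - q) <= abs(v[j] - q):
            j += 1
        picks[i] = idx[j]
        j += 1
    return picks


def select_stimuli(
    word_pool: Sequence[StimulusRecord],
    nonword_pool: Sequence[StimulusRecord],
    constraints: SelectionConstraints | None = None,
) -> tuple[list[StimulusRecord], list[StimulusRecord]]:
    """Select n words and n nonwords meeting the distributional constraints.

    Returns ``(words, nonwords)``, each of length ``n_per_class``, whose
    z-GLA samples jointly pass Shapiro-Wilk normality, a Welch mean
    difference and median-centered Levene variance equality at the
    configured alphas. Raises :class:`SelectionError` (carrying the best
    attempt's p-values) if the budget is exhausted.
    """
    c = constraints or SelectionConstraints()
    n = c.n_per_class
    if len(word_pool) < n or len(nonword_pool) < n:
        raise ValueError(
            f"pools of {len(word_pool)}/{len(nonword_pool)} cannot supply "
            f"{n} items per class"
        )
    wv = np.array([r.gla_z for r in word_pool])
    nv = np.array([r.gla_z for r in nonword_pool])

    # identity shortcut: pools already exactly the requested samples
    if len(word_pool) == n and len(nonword_pool) == n:
        ok, pvals = _audit(wv, nv, c)
        if ok:
            return list(word_pool), list(nonword_pool)

    rng = np.random.default_rng(c.seed)
    w_avail = np.arange(len(wv))
    n_avail = np.arange(len(nv))

    iqr_w = float(np.subtract(*np.percentile(wv, [75, 25])))
    iqr_n = float(np.subtract(*np.percentile(nv, [75, 25])))
    s_ref = max(min(iqr_w, iqr_n) / 1.349, 1e-12)
    # mean separation that keeps the Welch test decisively significant
    t_needed = stats.t.ppf(1 - c.mean_diff_alpha / 2, df=2 * n - 2) + 1.0

    grid = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    best: tuple[float, dict] | None = None

    def propose(scale: float, pct_w: float, pct_n: float, jitter: float = 0.0):
        s_it = s_ref * scale
        mw = float(np.percentile(wv[w_avail], pct_w)) + jitter
        mn = float(np.percentile(nv[n_avail], pct_n)) - jitter
        min_sep = t_needed * s_it * math.sqrt(2.0 / n)
        if abs(mw - mn) < min_sep:
            mid, sign = 0.5 * (mw + mn), (1.0 if mw >= mn else -1.0)
            mw = mid + sign * min_sep / 2
            mn = mid - sign * min_sep / 2
        wi = _match_quantiles(wv, w_avail, mw + s_it * grid)
        ni = _match_quantiles(nv, n_avail, mn + s_it * grid)
        return wi, ni

    # deterministic grid over the target sd and per-class centers (the GLA
    # distributions are lumpy, so the best normal window must be searched),
    # then seeded random proposals with trimming of extreme tails
    proposals = [
        (scale, pw, pn)
        for scale in (0.85, 0.95, 1.05, 0.75, 0.65, 0.55)
        for pw in (50, 45, 55, 60, 40)
        for pn in (60, 70, 80, 50, 55, 65, 75, 85, 45, 40, 35)
    ]
    for it in range(c.max_iterations):
        if it < len(proposals):
            scale, pw, pn = proposals[it]
            jitter = 0.0
        else:
            scale = float(rng.uniform(0.5, 1.0))
            pw = float(rng.uniform(35, 65))
            pn = float(rng.uniform(30, 70))
            jitter = float(rng.normal(0.0, 0.05 * s_ref))
        wi, ni = propose(scale, pw, pn, jitter)
        ok, pvals = _audit(wv[wi], nv[ni], c)
        if ok:
            return [word_pool[i] for i in wi], [nonword_pool[i] for i in ni]
        score = min(
            pvals["shapiro_words"], pvals["shapiro_nonwords"], pvals["levene"],
            1.0 - pvals["welch"],
        )
        if best is None or score > best[0]:
            best = (score, pvals)
        # trimming heuristic: drop extreme tail candidates of a class that
        # keeps failing normality (only during the random phase)
        if it >= len(proposals):
            if pvals["shapiro_words"] <= c.normality_alpha and len(w_avail) > n + 2:
                center = float(np.median(wv[w_avail]))
                extreme = np.argsort(-np.abs(wv[w_avail] - center))[:2]
                w_avail = np.delete(w_avail, extreme)
            if pvals["shapiro_nonwords"] <= c.normality_alpha and len(n_avail) > n + 2:
                center = float(np.median(nv[n_avail]))
                extreme = np.argsort(-np.abs(nv[n_avail] - center))[:2]
                n_avail = np.delete(n_avail, extreme)

    raise SelectionError(
        f"selection constraints not met within {c.max_iterations} iterations",
        diagnostics=best[1] if best else {},
    )


def assign_gla_levels(records: Sequence[StimulusRecord], k: int = 3) -> list[StimulusRecord]:
    """Assign low/medium/high GLA tertiles within one lexicality.

    Records are ranked by z-GLA (stable on input order for ties); the
    bottom third becomes *low*, the top third *high*, the rest *medium*.
    Level sizes differ by at most one (remainders go to low, then high).
    """
    if k != 3:
        raise ValueError("only tertile (k=3) leveling is supported")
    lexicalities = {r.lexicality for r in records}
    if len(lexicalities) != 1:
        raise ValueError("records must be of a single lexicality")
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records")
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_high = base + (1 if rem == 2 else 0)
    order = sorted(range(n), key=lambda i: (records[i].gla_z, i))
    out = list(records)
    for rank, i in enumerate(order):
        if rank < n_low:
            level = "low"
        elif rank >= n - n_high:
            level = "high"
        else:
            level = "medium"
        out[i] = replace(records[i], level=level)
    return out


def stimulus_frame(records: Sequence[StimulusRecord]) -> pd.DataFrame:
    """Flat table of records with the standard measure columns."""
    rows = []
    for r in records:
        m = r.measures.as_dict() if r.measures is not None else {}
        rows.append(
            {"word": r.string, "lexicality": r.lexicality,
             "GLA": r.gla_raw, "GLAz": r.gla_z, "level": r.level, **m}
        )
    return pd.DataFrame(rows).reindex(columns=MEASURE_COLUMNS)


def descriptor_table(records: Sequence[StimulusRecord]) -> pd.DataFrame:
    """Per lexicality x GLA-level means of the psycholinguistic measures.

    Frequency columns (LogF, Fmio) are blank for nonwords, which have no
    lexical frequency.
    """
    if any(r.level is None for r in records):
        raise ValueError("levels not assigned")
    if any(r.measures is None for r in records):
        raise ValueError("measures missing")
    df = stimulus_frame(records)
    counts = df.groupby(["lexicality", "level"], observed=True).size()
    expected = {(lex, lvl) for lex in df["lexicality"].unique() for lvl in LEVELS}
    missing = expected - set(counts.index)
    if missing:
        raise ValueError(f"empty lexicality/level cell(s): {sorted(missing)}")
    cols = ["GLA", "LogF", "Fmio", "N", "FN", "BiC", "BiF"]
    df["level"] = pd.Categorical(df["level"], categories=list(LEVELS), ordered=True)
    table = df.groupby(["lexicality", "level"], observed=True)[cols].mean()
    return table.sort_index()


def gla_correlations(records: Sequence[StimulusRecord]) -> pd.DataFrame:
    """Pearson r of raw GLA with each orthographic measure, per lexicality.

    Constant measures yield an undefined (NaN) correlation.
    """
    if any(r.measures is None for r in records):
        raise ValueError("measures missing")
    out = {}
    for lex in ("word", "nonword"):
        subset = [r for r in records if r.lexicality == lex]
        if not subset:
            continue
        if len(subset) < 3:
            raise ValueError(f"need >= 3 {lex} records for correlations")
        gla = np.array([r.gla_raw for r in subset])
        col = {}
        for m in _CORR_MEASURES:
            x = np.array([float(getattr(r.measures, m)) for r in subset])
            if np.ptp(x) == 0 or np.ptp(gla) == 0:
                col[m] = np.nan
            else:
                col[m] = float(stats.pearsonr(gla, x).statistic)
        out[lex] = col
    return pd.DataFrame(out).reindex(_CORR_MEASURES)


def build_stimulus_set(
    lexicon: Lexicon,
    *,
    n_words: int = 300,
    n_nonwords: int = 300,
    pool_size: int = 2000,
    seed: int = 0,
    params: ModelParams | None = None,
    constraints: SelectionConstraints | None = None,
    word_length: int = 4,
) -> tuple[list[StimulusRecord], list[StimulusRecord]]:
    """End-to-end pipeline from a lexicon to a leveled stimulus set.

    Takes every *word_length*-letter lexicon word as the word candidate
    pool, generates *pool_size* nonwords, simulates GLA for the joint
    pool, z-scores jointly, applies the constrained selection and assigns
    within-lexicality tertile levels. Orthographic measures are attached
    to the selected records only (the expensive part of the table).
    """
    words = list(lexicon.words_of_length(word_length))
    if len(words) < n_words:
        raise ValueError(
            f"lexicon has only {len(words)} {word_length}-letter words; need {n_words}"
        )
    nonwords = generate_nonword_pool(words, lexicon, pool_size, seed)
    model = InteractiveActivationModel(lexicon, params)
    all_stims = words + nonwords
    raw = np.array([model.gla(s) for s in all_stims])
    z = z_transform(raw)

    word_pool = [
        StimulusRecord(w, "word", float(raw[i]), float(z[i]))
        for i, w in enumerate(words)
    ]
    nonword_pool = [
        StimulusRecord(nw, "nonword", float(raw[len(words) + i]), float(z[len(words) + i]))
        for i, nw in enumerate(nonwords)
    ]
    if constraints is None:
        constraints = SelectionConstraints(seed=seed)
    if constraints.n_per_class != n_words:
        constraints = replace(constraints, n_per_class=n_words)
    if n_words != n_nonwords:
        raise ValueError("n_words and n_nonwords must match (one constraint set)")

    sel_words, sel_nonwords = select_stimuli(word_pool, nonword_pool, constraints)
    sel_words = assign_gla_levels(sel_words)
    sel_nonwords = assign_gla_levels(sel_nonwords)

    sel_words = [
        replace(r, measures=ortho_measures(r.string, lexicon, lexicon.frequency(r.string)))
        for r in sel_words
    ]
    sel_nonwords = [
        replace(r, measures=ortho_measures(r.string, lexicon, None))
        for r in sel_nonwords
    ]
    return sel_words, sel_nonwords
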