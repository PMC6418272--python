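"""Interactive-activation network with multiple read-out lexical decision.

The network has position-specific letter units (one per position x
alphabet letter) and one unit per lexicon word. Connectivity follows the
interactive-activation architecture: a word of length L is excited by its
own letter-at-position units for positions 1..L, inhibited by every other
letter unit at those positions, laterally inhibited by all other word
units, and feeds excitation back to its own letters. Letter evidence is
clamped directly at the letter units (matching letter at each stimulus
position driven positively, the competing letters at that position driven
negatively); there is no separate visual-feature layer.

Cycle dynamics are synchronous. With net input ``n`` computed from the
positive-part ("active senders only") activations of the previous cycle,

    da = n * (a_max - a) - decay * (a - rest)    if n > 0
    da = n * (a - a_min) - decay * (a - rest)    otherwise

and activations are clipped to ``[a_min, a_max]``. Word resting levels
scale linearly with log frequency (the most frequent word rests at the
top of ``rest_range``).

**Global lexical activity** (GLA) is the mean, over the first
``gla_cycles`` post-stimulus cycles, of the summed positive word-unit
activation — a single familiarity/wordlikeness estimate of the stimulus.

**Lexical decision** uses three read-out criteria checked each cycle in
order: M (any single word unit reaches the identification threshold ->
YES), S (instantaneous summed positive word activity reaches a global
threshold -> YES, the "fast guess"), and T (a temporal deadline -> NO).
Early in processing (``adjust_cycle``) the momentary global activity g is
read out and shifts the other two criteria: high g lowers the S threshold
and delays the T deadline, so wordlike stimuli are fast-guessed YES and
take longer to reject.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .lexicon import Lexicon, log_frequency

__all__ = [
    "ModelParams",
    "ActivationTrace",
    "DecisionOutcome",
    "InteractiveActivationModel",
    "build_network",
    "run_trial",
    "global_lexical_activity",
    "z_transform",
    "simulate_lexical_decision",
    "activation_step",
]


@dataclass(frozen=True)
class ModelParams:
    """Network gains, bounds and read-out criteria.

    Connection gains and bounds are the conventional interactive-activation
    values; the read-out parameters (``m_criterion``, ``s_*``, ``t_*``)
    govern the simulated lexical decision. All are configurable.
    """

    excite_letter_word: float = 0.07
    inhibit_letter_word: float = 0.04
    inhibit_word_word: float = 0.10
    feedback_word_letter: float = 0.30
    decay: float = 0.07
    a_max: float = 1.0
    a_min: float = -0.2
    rest_range: tuple[float, float] = (-0.92, 0.0)
    input_clamp: float = 1.0
    gla_cycles: int = 7
    m_criterion: float = 0.55
    s_base: float = 1.1
    s_gain: float = 1.5
    s_min: float = 0.4
    t_base: int = 20
    t_gain: float = 10.0
    adjust_cycle: int = 3

    def __post_init__(self) -> None:
        if not (self.a_min < 0 <= self.a_max):
            raise ValueError("require a_min < 0 <= a_max")
        if not (self.rest_range[0] <= self.rest_range[1] <= 0):
            raise ValueError("rest_range must lie at or below zero")
        if not (0 <= self.m_criterion <= self.a_max):
            raise ValueError("m_criterion must lie in [0, a_max]")
        if self.gla_cycles < 1:
            raise ValueError("gla_cycles >= 1")
        if self.t_base < 1:
            raise ValueError("t_base >= 1")
        if self.adjust_cycle < 1:
            raise ValueError("adjust_cycle >= 1")
        for gain in ("excite_letter_word", "inhibit_letter_word",
                     "inhibit_word_word", "feedback_word_letter", "decay"):
            if getattr(self, gain) < 0:
                raise ValueError(f"{gain} must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Read a flat ``key = value`` config file (sections optional)."""
        cp = configparser.ConfigParser()
        text = Path(path).read_text(encoding="utf-8")
        if not text.lstrip().startswith("["):
            text = "[params]\n" + text
        cp.read_string(text)
        flat: dict[str, str] = {}
        for section in cp.sections():
            flat.update(cp.items(section))
        kwargs: dict[str, object] = {}
        valid = {f.name: f for f in fields(cls)}
        for key, value in flat.items():
            if key not in valid:
                raise ValueError(f"unknown parameter {key!r}")
            if key == "rest_range":
                lo, hi = (float(v) for v in value.replace("(", "").replace(")", "").split(","))
                kwargs[key] = (lo, hi)
            elif key in ("gla_cycles", "t_base", "adjust_cycle"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = ["[params]"]
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = f"{v[0]}, {v[1]}"
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def activation_step(
    a: np.ndarray | float,
    net: np.ndarray | float,
    rest: np.ndarray | float,
    params: ModelParams,
) -> np.ndarray:
    """One synchronous activation update, clipped to ``[a_min, a_max]``.

    With constant positive net input ``n`` a single unit converges to the
    fixed point ``(n * a_max + decay * rest) / (n + decay)``.
    """
    a = np.asarray(a, dtype=float)
    net = np.asarray(net, dtype=float)
    da = np.where(
        net > 0,
        net * (params.a_max - a),
        net * (a - params.a_min),
    ) - params.decay * (a - rest)
    return np.clip(a + da, params.a_min, params.a_max)


@dataclass
class ActivationTrace:
    """Per-cycle unit activations for one stimulus presentation.

    ``letters`` has shape ``(n_cycles + 1, positions, alphabet)`` and
    ``words`` shape ``(n_cycles + 1, n_words)``; row 0 is the resting
    state, row c the state after cycle c.
    """

    stimulus: str
    letters: np.ndarray
    words: np.ndarray
    word_labels: tuple[str, ...]
    params: ModelParams

    @property
    def n_cycles(self) -> int:
        return self.words.shape[0] - 1

    def word_activation(self, word: str) -> np.ndarray:
        return self.words[:, self.word_labels.index(word)]

    def summed_positive(self) -> np.ndarray:
        """Summed positive word activation per cycle (index 0 = rest)."""
        return np.clip(self.words, 0.0, None).sum(axis=1)


@dataclass(frozen=True)
class DecisionOutcome:
    """Simulated lexical-decision response.

    ``criterion`` is M (single-word identification, YES), S (global fast
    guess, YES) or T (temporal deadline, NO); ``gla_at_adjust`` is the
    momentary global activity read at the adjustment cycle.
    """

    response: str
    rt_cycles: int
    criterion: str
    gla_at_adjust: float

    def __post_init__(self) -> None:
        if self.criterion not in ("M", "S", "T"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        expected = "NO" if self.criterion == "T" else "YES"
        if self.response != expected:
            raise ValueError(f"criterion {self.criterion} implies {expected}")
        if self.rt_cycles < 1:
            raise ValueError("rt_cycles >= 1")


class InteractiveActivationModel:
    """Interactive-activation network over a lexicon.

    Parameters
    ----------
    lexicon
        The word layer; one unit per entry.
    params
        Gains, bounds and read-out criteria (defaults are conventional).
    """

    def __init__(self, lexicon: Lexicon, params: ModelParams | None = None):
        if len(lexicon) == 0:
            raise ValueError("empty lexicon")
        self.lexicon = lexicon
        self.params = params or ModelParams()
        self.alphabet: tuple[str, ...] = tuple(sorted(lexicon.alphabet))
        self._letter_index = {c: i for i, c in enumerate(self.alphabet)}
        self.n_positions = max(len(w) for w in lexicon.words)
        K, P, W = len(self.alphabet), self.n_positions, len(lexicon)

        # E[w, p*K + a] = 1 iff word w has letter a at position p
        E = np.zeros((W, P * K))
        pos_mask = np.zeros((W, P))
        for wi, word in enumerate(lexicon.words):
            for p, ch in enumerate(word):
                E[wi, p * K + self._letter_index[ch]] = 1.0
                pos_mask[wi, p] = 1.0
        self._E = E
        self._pos_mask = pos_mask

        logf = np.array([log_frequency(f) for f in lexicon.frequencies])
        lo, hi = self.params.rest_range
        span = logf.max() - logf.min()
        if span > 0:
            self.rest = lo + (logf - logf.min()) / span * (hi - lo)
        else:
            self.rest = np.full(W, hi)  # equal (or single) frequencies rest at top
        # the realized resting state honours the activation bounds; rest levels
        # below a_min act as a stronger pull in the decay term only
        self.resting_state = np.clip(self.rest, self.params.a_min, self.params.a_max)

    # -- dynamics -----------------------------------------------------------
    def _external_input(self, stimulus: str) -> np.ndarray:
        K = len(self.alphabet)
        ext = np.zeros(self.n_positions * K)
        for p, ch in enumerate(stimulus):
            ext[p * K : (p + 1) * K] = -self.params.input_clamp
            ext[p * K + self._letter_index[ch]] = self.params.input_clamp
        return ext

    def _validate_stimulus(self, stimulus: str) -> str:
        stimulus = stimulus.lower()
        if len(stimulus) > self.n_positions:
            raise ValueError(
                f"stimulus {stimulus!r} longer than {self.n_positions} position channels"
            )
        bad = set(stimulus) - set(self.alphabet)
        if bad:
            raise ValueError(f"stimulus letters outside alphabet: {sorted(bad)}")
        return stimulus

    def _iter_states(self, stimulus: str) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Yield (letter, word) activation vectors after each cycle, forever."""
        p = self.params
        ext = self._external_input(stimulus)
        K = len(self.alphabet)
        L = np.zeros(self.n_positions * K)
        Wd = self.resting_state.copy()
        while True:
            lp = np.clip(L, 0.0, None)
            wp = np.clip(Wd, 0.0, None)
            per_pos = lp.reshape(self.n_positions, K).sum(axis=1)
            match = self._E @ lp
            net_w = (
                (p.excite_letter_word + p.inhibit_letter_word) * match
                - p.inhibit_letter_word * (self._pos_mask @ per_pos)
                - p.inhibit_word_word * (wp.sum() - wp)
            )
            net_l = p.feedback_word_letter * (self._E.T @ wp) + ext
            Wd = activation_step(Wd, net_w, self.rest, p)
            L = activation_step(L, net_l, 0.0, p)
            yield L, Wd

    def run_trial(self, stimulus: str, n_cycles: int) -> ActivationTrace:
        """Present *stimulus* for *n_cycles* synchronous cycles.

        Cycle 0 of the returned trace is the resting state.
        """
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        stimulus = self._validate_stimulus(stimulus)
        K = len(self.alphabet)
        letters = np.zeros((n_cycles + 1, self.n_positions, K))
        words = np.zeros((n_cycles + 1, len(self.lexicon)))
        words[0] = self.resting_state
        for c, (L, Wd) in zip(range(1, n_cycles + 1), self._iter_states(stimulus)):
            letters[c] = L.reshape(self.n_positions, K)
            words[c] = Wd
        return ActivationTrace(
            stimulus=stimulus,
            letters=letters,
            words=words,
            word_labels=self.lexicon.words,
            params=self.params,
        )

    # -- read-out -----------------------------------------------------------
    def gla(self, stimulus: str, window: int | None = None) -> float:
        """Raw global lexical activity of *stimulus* (see module docstring)."""
        window = window or self.params.gla_cycles
        return global_lexical_activity(self.run_trial(stimulus, window), window)

    def simulate_gla(
        self,
        stimuli: Sequence[str],
        lexicalities: Sequence[str] | None = None,
        window: int | None = None,
    ) -> pd.DataFrame:
        """GLA (raw and jointly z-scored) for a list of stimuli."""
        if lexicalities is None:
            lexicalities = ["word" if s in self.lexicon else "nonword" for s in stimuli]
        raw = np.array([self.gla(s, window) for s in stimuli])
        return pd.DataFrame(
            {
                "stimulus": list(stimuli),
                "lexicality": list(lexicalities),
                "GLA": raw,
                "GLAz": z_transform(raw),
            }
        )

    def decide(self, stimulus: str, max_cycles: int = 1000) -> DecisionOutcome:
        """Simulated lexical decision via the M, S and T read-out criteria."""
        p = self.params
        stimulus = self._validate_stimulus(stimulus)
        deadline = float(p.t_base)
        s_threshold = p.s_base
        g_adjust = 0.0
        for cycle, (L, Wd) in zip(range(1, max_cycles + 1), self._iter_states(stimulus)):
            spos = float(np.clip(Wd, 0.0, None).sum())
            if cycle == p.adjust_cycle:
                g_adjust = spos
                deadline = max(cycle, round(p.t_base + p.t_gain * g_adjust))
                s_threshold = max(p.s_min, p.s_base - p.s_gain * g_adjust)
            if (Wd >= p.m_criterion).any():
                return DecisionOutcome("YES", cycle, "M", g_adjust)
            if spos >= s_threshold:
                return DecisionOutcome("YES", cycle, "S", g_adjust)
            if cycle >= deadline:
                return DecisionOutcome("NO", cycle, "T", g_adjust)
        raise RuntimeError(f"no criterion reached within {max_cycles} cycles")


def build_network(lexicon: Lexicon, params: ModelParams | None = None) -> InteractiveActivationModel:
    """Construct the interactive-activation network for *lexicon*."""
    return InteractiveActivationModel(lexicon, params)


def run_trial(stimulus: str, network: InteractiveActivationModel, n_cycles: int) -> ActivationTrace:
    return network.run_trial(stimulus, n_cycles)


def global_lexical_activity(trace: ActivationTrace, window: int = 7) -> float:
    """Mean summed positive word activation over cycles 1..window.

    Cycle 0 (the resting state) is excluded from the average.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > trace.n_cycles:
        raise ValueError(f"window {window} exceeds trace length {trace.n_cycles}")
    return float(trace.summed_positive()[1 : window + 1].mean())


def z_transform(values: Iterable[float]) -> np.ndarray:
    """Standardize to mean 0, sample (n-1 denominator) sd 1."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-transform undefined")
    return (x - x.mean()) / sd


def simulate_lexical_decision(
    stimulus: str,
    network: InteractiveActivationModel,
    params: ModelParams | None = None,
) -> DecisionOutcome:
    """Lexical decision for *stimulus*; *params* overrides the network's."""
    if params is not None and params is not network.params:
        network = InteractiveActivationModel(network.lexicon, params)
    return network.decide(stimulus)
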