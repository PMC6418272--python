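"""Lexicon handling and orthographic similarity statistics.

A :class:`Lexicon` is an ordered collection of unique lowercase letter
strings with token frequencies (occurrences per million). It is both the
word layer of the interactive-activation network and the reference set
against which all orthographic statistics are computed:

* Coltheart's **N** — the number of same-length words reachable by a
  single letter substitution — together with the summed frequency of
  those neighbors (**FN**), the number of neighbors more frequent than
  the target (**NHF**) and their summed frequency (**FHN**).
* Bigram statistics: how often the target's adjacent ordered letter
  pairs occur in other words (**BiC**), how many other words share at
  least one such pair (**BiN**), and the summed frequency of those
  sharing words (**BiF**).

Nonwords have no frequency of their own; their higher-frequency-neighbor
statistics are computed against an implicit frequency of zero, so every
neighbor counts as higher-frequency (NHF = N, FHN = FN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Lexicon",
    "LexiconError",
    "DegenerateInputError",
    "OrthoMeasures",
    "RejectedRow",
    "read_lexicon",
    "neighbors",
    "ortho_measures",
    "log_frequency",
]


class LexiconError(ValueError):
    """Invalid lexicon file or lexicon invariant violation."""


class DegenerateInputError(ValueError):
    """Input too short/degenerate for the requested statistic."""


@dataclass(frozen=True)
class RejectedRow:
    """One input row dropped during validation, with its 1-based line number."""

    line: int
    word: str
    reason: str


@dataclass(frozen=True)
class Lexicon:
    """Ordered, validated word/frequency list.

    Parameters
    ----------
    entries
        Tuple of ``(word, freq_per_million)`` pairs, words lowercase.
    alphabet
        Allowed letters. Defaults to the letters occurring in the entries.
    length_bounds
        Inclusive ``(min, max)`` word length; entries outside are invalid.
    rejections
        Report of rows dropped while reading a file (informational).
    """

    entries: tuple[tuple[str, float], ...]
    alphabet: frozenset[str] = frozenset()
    length_bounds: tuple[int, int] = (3, 5)
    rejections: tuple[RejectedRow, ...] = ()

    def __post_init__(self) -> None:
        if not self.entries:
            raise LexiconError("empty lexicon")
        if not self.alphabet:
            letters = frozenset("".join(w for w, _ in self.entries))
            object.__setattr__(self, "alphabet", letters)
        lo, hi = self.length_bounds
        seen: set[str] = set()
        for word, freq in self.entries:
            if word in seen:
                raise LexiconError(f"duplicate word: {word!r}")
            seen.add(word)
            if word != word.lower():
                raise LexiconError(f"word not lowercase: {word!r}")
            if not lo <= len(word) <= hi:
                raise LexiconError(
                    f"word {word!r} violates length bounds {self.length_bounds}"
                )
            bad = set(word) - self.alphabet
            if bad:
                raise LexiconError(f"word {word!r} uses letters outside alphabet: {sorted(bad)}")
            if not (freq >= 0):
                raise LexiconError(f"negative or non-numeric frequency for {word!r}")
        object.__setattr__(self, "_index", {w: f for w, f in self.entries})

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[str, float]],
        alphabet: Iterable[str] | None = None,
        length_bounds: tuple[int, int] = (3, 5),
    ) -> "Lexicon":
        return cls(
            entries=tuple((w.lower(), float(f)) for w, f in entries),
            alphabet=frozenset(alphabet) if alphabet is not None else frozenset(),
            length_bounds=length_bounds,
        )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.words)

    def __contains__(self, word: object) -> bool:
        return word in self._index  # type: ignore[attr-defined]

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.entries)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for _, f in self.entries)

    def frequency(self, word: str) -> float:
        return self._index[word]  # type: ignore[attr-defined]

    def words_of_length(self, n: int) -> tuple[str, ...]:
        return tuple(w for w in self.words if len(w) == n)


def log_frequency(freq_per_million: float) -> float:
    """log10(freq + 1); the +1 offset keeps zero-frequency entries finite."""
    return math.log10(freq_per_million + 1.0)


def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [c.strip() for c in line.split(sep)]


def read_lexicon(
    path: str | Path,
    length_bounds: tuple[int, int] = (3, 5),
    alphabet: Iterable[str] | None = None,
) -> Lexicon:
    """Read a two-column delimited text file of ``word, freq_per_million``.

    Tab- or comma-delimited, UTF-8, optional header row. Rows whose word
    violates the length bounds or the alphabet are dropped and reported in
    ``Lexicon.rejections`` (with their line numbers); duplicate words and
    non-numeric frequencies are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    allowed = frozenset(alphabet) if alphabet is not None else None

    entries: list[tuple[str, float]] = []
    rejected: list[RejectedRow] = []
    lo, hi = length_bounds
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = _split_row(line)
            if len(cells) < 2:
                raise LexiconError(f"line {lineno}: expected two columns, got {line!r}")
            word, freq_str = cells[0].lower(), cells[1]
            try:
                freq = float(freq_str)
            except ValueError:
                if lineno == 1 and not entries:
                    continue  # header row
                raise LexiconError(f"line {lineno}: non-numeric frequency {freq_str!r}")
            if not lo <= len(word) <= hi:
                rejected.append(RejectedRow(lineno, word, f"length {len(word)} outside {length_bounds}"))
                continue
            if not word.isalpha():
                rejected.append(RejectedRow(lineno, word, "non-letter characters"))
                continue
            if allowed is not None and not set(word) <= allowed:
                rejected.append(RejectedRow(lineno, word, "letters outside alphabet"))
                continue
            if freq < 0:
                raise LexiconError(f"line {lineno}: negative frequency for {word!r}")
            entries.append((word, freq))

    if not entries:
        raise LexiconError(f"{path}: no valid entries")
    words = [w for w, _ in entries]
    dupes = {w for w in words if words.count(w) > 1}
    if dupes:
        raise LexiconError(f"duplicate word(s): {sorted(dupes)}")
    return Lexicon(
        entries=tuple(entries),
        alphabet=frozenset(allowed) if allowed is not None else frozenset(),
        length_bounds=length_bounds,
        rejections=tuple(rejected),
    )


def neighbors(target: str, lexicon: Lexicon) -> list[str]:
    """Same-length lexicon words at Hamming distance exactly 1 from *target*.

    The target itself is never included (a word is not its own neighbor);
    comparison is restricted to words of identical length (substitution
    neighbors, no insertions or deletions).
    """
    if not target:
        raise DegenerateInputError("empty target")
    target = target.lower()
    n = len(target)
    out = []
    for w in lexicon.words:
        if len(w) != n or w == target:
            continue
        diff = 0
        for a, b in zip(w, target):
            if a != b:
                diff += 1
                if diff > 1:
                    break
        if diff == 1:
            out.append(w)
    return out


@dataclass(frozen=True)
class OrthoMeasures:
    """Orthographic similarity statistics of one letter string.

    ``LogF``/``Fmio`` are ``None`` for nonwords (no lexical frequency).
    """

    N: int
    FN: float
    NHF: int
    FHN: float
    BiC: int
    BiF: float
    BiN: int
    LogF: float | None = None
    Fmio: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "LogF": self.LogF,
            "Fmio": self.Fmio,
            "N": self.N,
            "FN": self.FN,
            "NHF": self.NHF,
            "FHN": self.FHN,
            "BiC": self.BiC,
            "BiF": self.BiF,
            "BiN": self.BiN,
        }


def _bigrams(s: str) -> list[str]:
    return [s[i : i + 2] for i in range(len(s) - 1)]


def ortho_measures(
    target: str,
    lexicon: Lexicon,
    target_freq: float | None = None,
    *,
    position_specific: bool = False,
    bigram_counting: str = "token",
) -> OrthoMeasures:
    """All orthographic measures of *target* against *lexicon*.

    Parameters
    ----------
    target_freq
        The target's own frequency per million; ``None`` for nonwords, in
        which case higher-frequency-neighbor statistics treat the target
        as frequency 0 (every neighbor is "higher frequency").
    position_specific
        If True, a bigram only matches at the same within-string position;
        the default matches the classic position-independent bigram count.
    bigram_counting
        ``"token"`` counts every occurrence of a target bigram in another
        word (multiplicity included); ``"type"`` counts each distinct
        shared target bigram once per word.
    """
    if len(target) < 2:
        raise DegenerateInputError(f"target {target!r} too short for bigrams")
    if bigram_counting not in ("token", "type"):
        raise ValueError(f"unknown bigram_counting {bigram_counting!r}")
    target = target.lower()

    nbrs = neighbors(target, lexicon)
    ref_freq = 0.0 if target_freq is None else float(target_freq)
    n = len(nbrs)
    fn = sum(lexicon.frequency(w) for w in nbrs)
    higher = [w for w in nbrs if lexicon.frequency(w) > ref_freq]
    nhf = len(higher)
    fhn = sum(lexicon.frequency(w) for w in higher)

    if position_specific:
        tset = {(i, bg) for i, bg in enumerate(_bigrams(target))}
    else:
        tset = set(_bigrams(target))

    bic = 0
    bif = 0.0
    bin_ = 0
    for word, freq in lexicon.entries:
        if word == target:
            continue
        if position_specific:
            occ = [(i, bg) for i, bg in enumerate(_bigrams(word)) if (i, bg) in tset]
            hits = len(occ) if bigram_counting == "token" else len(set(occ))
        else:
            wbgs = _bigrams(word)
            if bigram_counting == "token":
                hits = sum(1 for bg in wbgs if bg in tset)
            else:
                hits = len(set(wbgs) & tset)
        if hits:
            bic += hits
            bin_ += 1
            bif += freq

    logf = log_frequency(ref_freq) if target_freq is not None else None
    return OrthoMeasures(
        N=n, FN=fn, NHF=nhf, FHN=fhn, BiC=bic, BiF=bif, BiN=bin_,
        LogF=logf, Fmio=target_freq if target_freq is None else float(target_freq),
    )
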