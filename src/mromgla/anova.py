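"""Region-level 2 x 3 repeated-measures trend analysis.

Consumes balanced per-subject signal-change tables (subject x lexicality
{word, nonword} x GLA level {low, medium, high}) extracted from a brain
region, and computes:

* the two-factor within-subject ANOVA, each effect tested against its
  own subject-by-effect interaction error term (no sphericity
  correction by default, matching uncorrected df reporting);
* single-df polynomial trend contrasts on the ordered GLA levels
  (linear weights (-1, 0, +1), quadratic (+1, -2, +1)), each against
  its subject-by-contrast error — the orthogonal decomposition
  SS_linear + SS_quadratic = SS_GLA holds exactly;
* per-lexicality simple effects of GLA (slice-wise error term by
  default, pooled optional) with their own trend contrasts;
* a qualitative profile label summarizing which lexicality carries a
  linear GLA trend and in which direction.

The statsmodels-style entry point is
``RegionTrendModel(data).fit() -> RegionTrendResults`` with a
``summary()`` table; ``rm_anova_2x3``/``linear_contrast``/
``simple_effects`` are functional equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import LEVELS

__all__ = [
    "RegionSignalTable",
    "EffectTest",
    "AnovaResult",
    "RegionProfile",
    "RegionTrendModel",
    "RegionTrendResults",
    "rm_anova_2x3",
    "linear_contrast",
    "simple_effects",
    "classify_region_profile",
    "read_signal_table",
]

_LEXICALITIES = ("word", "nonword")
LINEAR_WEIGHTS = np.array([-1.0, 0.0, 1.0])
QUADRATIC_WEIGHTS = np.array([1.0, -2.0, 1.0])


class RegionSignalTable:
    """Balanced subject x lexicality x GLA-level signal values for one region.

    Wraps a long-format DataFrame with columns ``subject``, ``lexicality``
    (word/nonword), ``level`` (low/medium/high) and ``value``; every
    subject must contribute exactly one value per cell.
    """

    def __init__(self, data: pd.DataFrame, region: str = "region"):
        required = {"subject", "lexicality", "level", "value"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = data.copy()
        if set(df["lexicality"]) != set(_LEXICALITIES):
            raise ValueError(f"lexicality must cover {_LEXICALITIES}")
        if set(df["level"]) != set(LEVELS):
            raise ValueError(f"level must cover {LEVELS}")
        counts = df.groupby(["subject", "lexicality", "level"], observed=True).size()
        n_subj = df["subject"].nunique()
        if (counts != 1).any() or len(counts) != 6 * n_subj:
            raise ValueError("unbalanced table: each subject needs exactly 6 cells")
        self.subjects = tuple(sorted(df["subject"].unique()))
        if len(self.subjects) < 3:
            raise ValueError("need >= 3 subjects")
        self.region = region
        self.data = df
        wide = df.set_index(["subject", "lexicality", "level"])["value"]
        arr = np.empty((len(self.subjects), 2, 3))
        for si, s in enumerate(self.subjects):
            for li, lex in enumerate(_LEXICALITIES):
                for ji, lvl in enumerate(LEVELS):
                    arr[si, li, ji] = wide.loc[(s, lex, lvl)]
        self.values = arr  # (n_subjects, lexicality, level)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, region: str | None = None) -> "RegionSignalTable":
        if region is None and "region" in data.columns:
            regions = data["region"].unique()
            if len(regions) != 1:
                raise ValueError("multiple regions present; pass region=")
            region = str(regions[0])
        return cls(data, region=region or "region")


@dataclass(frozen=True)
class EffectTest:
    """One F test: effect and error sums of squares, df pair, F, p."""

    ss: float
    ss_error: float
    df: tuple[int, int]
    F: float
    p: float
    estimate: float | None = None  # contrast value (trend estimate) where applicable


def _ftest(ss: float, df1: int, ss_err: float, df2: int, estimate: float | None = None) -> EffectTest:
    ms, ms_err = ss / df1, ss_err / df2
    if ss <= 1e-300 or np.isclose(ss, 0.0, atol=1e-300):
        # no effect variance at all: F defined as 0 (covers the all-equal table)
        if ms_err == 0:
            return EffectTest(ss, ss_err, (df1, df2), 0.0, 1.0, estimate)
    if ms_err == 0:
        return EffectTest(ss, ss_err, (df1, df2), float("inf"), 0.0, estimate)
    F = ms / ms_err
    return EffectTest(ss, ss_err, (df1, df2), float(F), float(stats.f.sf(F, df1, df2)), estimate)


@dataclass(frozen=True)
class LexicalitySlice:
    """Per-lexicality simple effect of GLA with its trend contrasts."""

    simple: EffectTest
    linear: EffectTest
    quadratic: EffectTest


@dataclass(frozen=True)
class AnovaResult:
    """Full 2 x 3 within-subject ANOVA with trend decomposition."""

    n_subjects: int
    lexicality: EffectTest
    gla: EffectTest
    interaction: EffectTest
    linear: EffectTest            # pooled linear GLA contrast
    quadratic: EffectTest         # pooled quadratic GLA contrast
    word: LexicalitySlice
    nonword: LexicalitySlice
    region: str = "region"


def _contrast_test(scores: np.ndarray, weights: np.ndarray, m: int) -> EffectTest:
    """Single-df contrast from per-subject scores against subject-by-contrast error.

    *scores* are per-subject contrast values (weights applied to that
    subject's level means, averaged over *m* lexicalities); SS scaling
    follows the balanced-design convention so pooled linear + quadratic
    SS reproduce the omnibus GLA SS.
    """
    n = len(scores)
    wss = float(weights @ weights)
    mean = float(scores.mean())
    ss = n * m * mean ** 2 / wss
    ss_err = m * float(((scores - mean) ** 2).sum()) / wss
    return _ftest(ss, 1, ss_err, n - 1, estimate=mean)


def _oneway_rm(Y: np.ndarray) -> EffectTest:
    """One-way within-subject ANOVA on an (n_subjects, levels) array."""
    Y = Y - Y.mean()
    n, k = Y.shape
    grand = Y.mean()
    lvl = Y.mean(axis=0)
    subj = Y.mean(axis=1)
    ss_b = n * float(((lvl - grand) ** 2).sum())
    resid = Y - lvl[None, :] - subj[:, None] + grand
    ss_err = float((resid ** 2).sum())
    return _ftest(ss_b, k - 1, ss_err, (k - 1) * (n - 1))


def rm_anova_2x3(table: RegionSignalTable) -> AnovaResult:
    """Two-factor within-subject ANOVA with trend and simple-effect decomposition."""
    Y = table.values - table.values.mean()  # centering is SS-invariant, keeps
    n = table.n_subjects                    # degenerate (constant) tables exact
    grand = Y.mean()
    subj = Y.mean(axis=(1, 2))
    A = Y.mean(axis=(0, 2))       # lexicality means
    B = Y.mean(axis=(0, 1))       # level means
    AB = Y.mean(axis=0)           # (2, 3) cell means
    sA = Y.mean(axis=2)           # (n, 2)
    sB = Y.mean(axis=1)           # (n, 3)

    ss_a = 3 * n * float(((A - grand) ** 2).sum())
    ss_b = 2 * n * float(((B - grand) ** 2).sum())
    ss_ab = n * float(((AB - A[:, None] - B[None, :] + grand) ** 2).sum())
    ss_as = 3 * float(((sA - subj[:, None] - A[None, :] + grand) ** 2).sum())
    ss_bs = 2 * float(((sB - subj[:, None] - B[None, :] + grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subj = 6 * float(((subj - grand) ** 2).sum())
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    lex = _ftest(ss_a, 1, ss_as, n - 1)
    gla = _ftest(ss_b, 2, ss_bs, 2 * (n - 1))
    inter = _ftest(ss_ab, 2, ss_abs, 2 * (n - 1))

    pooled_lin = _contrast_test(sB @ LINEAR_WEIGHTS / 1.0, LINEAR_WEIGHTS, m=2)
    pooled_quad = _contrast_test(sB @ QUADRATIC_WEIGHTS, QUADRATIC_WEIGHTS, m=2)

    slices = {}
    for li, lexname in enumerate(_LEXICALITIES):
        S = Y[:, li, :]  # (n, 3)
        slices[lexname] = LexicalitySlice(
            simple=_oneway_rm(S),
            linear=_contrast_test(S @ LINEAR_WEIGHTS, LINEAR_WEIGHTS, m=1),
            quadratic=_contrast_test(S @ QUADRATIC_WEIGHTS, QUADRATIC_WEIGHTS, m=1),
        )

    return AnovaResult(
        n_subjects=n,
        lexicality=lex,
        gla=gla,
        interaction=inter,
        linear=pooled_lin,
        quadratic=pooled_quad,
        word=slices["word"],
        nonword=slices["nonword"],
        region=table.region,
    )


def linear_contrast(
    table: RegionSignalTable,
    lexicality: Literal["word", "nonword", "pooled"] = "pooled",
    weights: np.ndarray | None = None,
) -> EffectTest:
    """Polynomial trend contrast on the GLA levels.

    ``lexicality="pooled"`` averages word and nonword cells per subject;
    otherwise the named slice is used. Default weights are the linear
    (-1, 0, +1) set; pass ``QUADRATIC_WEIGHTS`` for the quadratic partner.
    """
    w = LINEAR_WEIGHTS if weights is None else np.asarray(weights, dtype=float)
    Y = table.values
    if lexicality == "pooled":
        scores = Y.mean(axis=1) @ w
        return _contrast_test(scores, w, m=2)
    li = _LEXICALITIES.index(lexicality)
    return _contrast_test(Y[:, li, :] @ w, w, m=1)


def simple_effects(
    table: RegionSignalTable,
    error: Literal["slicewise", "pooled"] = "slicewise",
) -> dict[str, EffectTest]:
    """Per-lexicality one-way within-subject GLA effect.

    The slice-wise error term (default) uses only that lexicality's
    subject-by-level residuals, df (2, 2(n-1)); the pooled option tests
    against the combined GLA and interaction error of the full design.
    """
    Y = table.values
    n = table.n_subjects
    out = {}
    if error == "pooled":
        full = rm_anova_2x3(table)
        ss_err = full.gla.ss_error + full.interaction.ss_error
        df_err = 4 * (n - 1)
    for li, lexname in enumerate(_LEXICALITIES):
        S = Y[:, li, :]
        if error == "slicewise":
            out[lexname] = _oneway_rm(S)
        else:
            grand = S.mean()
            ss_b = n * float(((S.mean(axis=0) - grand) ** 2).sum())
            out[lexname] = _ftest(ss_b, 2, ss_err, df_err)
    return out


@dataclass(frozen=True)
class RegionProfile:
    """Qualitative GLA-response pattern of a region."""

    label: str
    direction: str  # increasing | decreasing | none

    def __str__(self) -> str:
        return f"{self.label} ({self.direction})"


def classify_region_profile(result: AnovaResult, alpha: float = 0.05) -> RegionProfile:
    """Label a region by which lexicality carries a linear GLA trend.

    Per-lexicality linear contrasts decide first (a region whose words,
    but not nonwords, show a significant linear trend is
    ``word-specific-linear`` whether or not the omnibus interaction
    crosses alpha — interactions of this size are routinely marginal);
    both-significant gives ``shared-linear``; with no lexicality-specific
    trend, a significant GLA main effect is ``shared-linear`` if its
    pooled linear contrast is significant and ``interaction-nonlinear``
    if only the interaction (or a non-linear main effect) is present;
    otherwise ``null``. The attached direction is the sign of the
    relevant linear trend (high minus low GLA).
    """
    wl = result.word.linear
    nl = result.nonword.linear
    w_sig, n_sig = wl.p < alpha, nl.p < alpha

    def direction(est: float | None) -> str:
        if est is None or est == 0:
            return "none"
        return "increasing" if est > 0 else "decreasing"

    if w_sig and not n_sig:
        return RegionProfile("word-specific-linear", direction(wl.estimate))
    if n_sig and not w_sig:
        return RegionProfile("nonword-specific-linear", direction(nl.estimate))
    if w_sig and n_sig:
        return RegionProfile("shared-linear", direction(result.linear.estimate))
    if result.gla.p < alpha:
        if result.linear.p < alpha:
            return RegionProfile("shared-linear", direction(result.linear.estimate))
        return RegionProfile("interaction-nonlinear", "none")
    if result.interaction.p < alpha:
        return RegionProfile("interaction-nonlinear", "none")
    return RegionProfile("null", "none")


def read_signal_table(path) -> dict[str, RegionSignalTable]:
    """Read a long-format CSV/TSV `region, subject, lexicality, level, value`."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "region" not in df.columns:
        df["region"] = "region"
    return {
        str(region): RegionSignalTable(sub.drop(columns="region"), region=str(region))
        for region, sub in df.groupby("region", observed=True)
    }


class RegionTrendModel:
    """Repeated-measures trend model for one region's signal table.

    Examples
    --------
    >>> model = RegionTrendModel.from_dataframe(df)   # doctest: +SKIP
    >>> res = model.fit()                             # doctest: +SKIP
    >>> print(res.summary())                          # doctest: +SKIP
    """

    def __init__(self, data: RegionSignalTable | pd.DataFrame, region: str | None = None):
        if isinstance(data, pd.DataFrame):
            data = RegionSignalTable.from_dataframe(data, region=region)
        self.table = data

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, region: str | None = None) -> "RegionTrendModel":
        return cls(RegionSignalTable.from_dataframe(data, region=region))

    def fit(self, alpha: float = 0.05) -> "RegionTrendResults":
        result = rm_anova_2x3(self.table)
        profile = classify_region_profile(result, alpha=alpha)
        return RegionTrendResults(self, result, profile, alpha)


class RegionTrendResults:
    """Fitted trend analysis: F table, contrasts, profile, summary/plot."""

    def __init__(self, model: RegionTrendModel, anova: AnovaResult,
                 profile: RegionProfile, alpha: float):
        self.model = model
        self.anova = anova
        self.profile = profile
        self.alpha = alpha

    def effects_frame(self) -> pd.DataFrame:
        a = self.anova
        rows = {
            "lexicality": a.lexicality,
            "GLA": a.gla,
            "lexicality x GLA": a.interaction,
            "GLA linear (pooled)": a.linear,
            "GLA quadratic (pooled)": a.quadratic,
            "GLA | word": a.word.simple,
            "GLA linear | word": a.word.linear,
            "GLA | nonword": a.nonword.simple,
            "GLA linear | nonword": a.nonword.linear,
        }
        return pd.DataFrame(
            {
                "F": {k: t.F for k, t in rows.items()},
                "df1": {k: t.df[0] for k, t in rows.items()},
                "df2": {k: t.df[1] for k, t in rows.items()},
                "p": {k: t.p for k, t in rows.items()},
            }
        )

    def summary(self) -> str:
        df = self.effects_frame()
        lines = [
            f"Region trend analysis: {self.anova.region}",
            f"subjects: {self.anova.n_subjects}   alpha: {self.alpha}",
            "-" * 58,
            f"{'effect':<26}{'F':>9}{'df':>10}{'p':>12}",
        ]
        for name, row in df.iterrows():
            dfpair = f"({int(row.df1)}, {int(row.df2)})"
            lines.append(f"{name:<26}{row.F:>9.3f}{dfpair:>10}{row.p:>12.4f}")
        lines.append("-" * 58)
        lines.append(f"profile: {self.profile}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Level means per lexicality with across-subject SEM bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.5))
        Y = self.model.table.values
        x = np.arange(3)
        for li, (lex, marker) in enumerate(zip(_LEXICALITIES, ("o", "s"))):
            means = Y[:, li, :].mean(axis=0)
            sems = Y[:, li, :].std(axis=0, ddof=1) / np.sqrt(Y.shape[0])
            ax.errorbar(x, means, yerr=sems, marker=marker, capsize=3, label=lex)
        ax.set_xticks(x, LEVELS)
        ax.set_xlabel("GLA level")
        ax.set_ylabel("signal change (a.u.)")
        ax.set_title(f"{self.anova.region}: {self.profile.label}")
        ax.legend(frameon=False)
        return ax
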