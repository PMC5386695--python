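"""Two-group differential expression with a permutation-constructed null.

The model fitted here is the study's testing scheme for spike-in proteomics:

* missing values are drawn from a Gaussian downshifted below the observed
  distribution (missing-not-at-random: undetected proteins sit near or
  below the detection limit), with mean mu - 1.5*sigma and width 0.5*sigma
  of the *total* data matrix;
* each protein gets a two-sided equal-variance Student t-test between the
  two groups of biological replicates;
* significance is corrected by an empirical background built from random
  reassignments of the group labels, pooled across proteins (SAM-style):
  a protein is flagged when the chance of a statistic at least as extreme
  under that background stays below the chosen level. For a 3-vs-3 design
  all C(6,3) = 20 label assignments are enumerated exactly.
* a protein is called differentially expressed when |log2 difference| >=
  0.58 (1.5-fold) and p < 0.05; the stricter flag additionally requires
  the permutation criterion at FDR level 0.05.

`DifferentialExpression` is the model object; `fit()` returns a
`DifferentialExpressionResults` carrying the per-protein table, flags and
diagnostics. Both the imputed and unimputed analysis arms are computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleDesign
from .quant import QuantMatrix, format_fold, group_difference

__all__ = [
    "ImputationParams",
    "impute_downshift",
    "student_t",
    "t_statistics",
    "permutation_significance",
    "PermutationResult",
    "call_de",
    "exclusive_detection",
    "volcano_table",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]

#: All label assignments are enumerated exactly when their total count is
#: at most this; beyond it, random sampling with ``n_perm`` draws is used.
ENUMERATION_LIMIT = 10_000


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-Gaussian imputation parameters, in units of the
    whole-matrix standard deviation."""

    downshift: float = 1.5
    width: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def impute_downshift(
    matrix: QuantMatrix,
    params: ImputationParams | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Replace missing cells with draws from a downshifted Gaussian.

    The donor distribution is Normal(mu - downshift*sigma, (width*sigma)^2)
    where mu, sigma are the mean and SD of all observed values in the matrix.
    Observed cells are untouched. Returns the imputed matrix and a boolean
    mask of imputed positions; deterministic given the seed.
    """
    params = params or ImputationParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = matrix.data.to_numpy(copy=True)
    observed = np.isfinite(values)
    if observed.sum() < 2:
        raise ValueError("need >= 2 observed values to estimate matrix moments")
    mu = values[observed].mean()
    sigma = values[observed].std(ddof=1)
    if sigma == 0:
        raise ValueError("matrix standard deviation is zero; cannot impute")
    missing = ~observed
    values[missing] = rng.normal(
        mu - params.downshift * sigma, params.width * sigma, size=int(missing.sum())
    )
    imputed = pd.DataFrame(missing, index=matrix.data.index, columns=matrix.data.columns)
    out = QuantMatrix(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        matrix.source,
    )
    return out, imputed


def student_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided equal-variance two-sample Student t-test.

    Returns (t, p) with t oriented as mean(b) - mean(a). Raises on zero
    pooled variance, where the statistic is undefined (callers may impute
    first, which adds noise and removes the degeneracy).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (len(a) + len(b) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(b, a, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def t_statistics(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise equal-variance t statistics and two-sided p values.

    ``values`` is proteins x samples and must be complete for the indexed
    columns. ``s0`` is an optional additive variance-stabilizing constant on
    the denominator (0 by default: the plain Student statistic). Rows whose
    pooled variance is zero (and s0 == 0) yield NaN.
    """
    a = values[:, idx_a]
    b = values[:, idx_b]
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    sa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sp2 = (sa + sb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb)) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (b.mean(axis=1) - a.mean(axis=1)) / denom
    t = np.where(denom > 0, t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


@dataclass
class PermutationResult:
    """Outcome of the pooled permutation test."""

    sig: pd.Series  # boolean per protein
    empirical_p: pd.Series  # pooled-null tail probability of each |t|
    n_assignments: int  # label assignments used for the null
    exhaustive: bool
    fdr_estimate: float  # mean permutation calls / observed calls at the threshold


def _label_assignments(
    n: int, n_a: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Group-A index sets for the null: exhaustive if feasible, else sampled."""
    total = comb(n, n_a)
    if total <= ENUMERATION_LIMIT:
        sets = np.array(list(itertools.combinations(range(n), n_a)), dtype=int)
        return sets, True
    picks = np.empty((n_perm, n_a), dtype=int)
    for i in range(n_perm):
        picks[i] = np.sort(rng.choice(n, size=n_a, replace=False))
    return picks, False


def permutation_significance(
    matrix: QuantMatrix,
    design: SampleDesign,
    n_perm: int = 250,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    s0: float = 0.0,
) -> PermutationResult:
    """Flag proteins extreme against a pooled label-permutation background.

    For every label assignment (all of them when the count is small, e.g.
    the 20 assignments of a 3-vs-3 design), per-protein |t| statistics are
    computed and pooled into one empirical null. A protein's empirical p is
    the fraction of pooled null statistics at least as extreme as its
    observed |t|; it is flagged when that fraction is below ``alpha``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = matrix.samples
    groups = [design.group_of(s) for s in samples]
    a, b = design.groups
    idx_a = np.array([i for i, g in enumerate(groups) if g == a])
    idx_b = np.array([i for i, g in enumerate(groups) if g == b])
    values = matrix.data.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("matrix must be complete (impute first) for the permutation test")

    t_obs, _ = t_statistics(values, idx_a, idx_b, s0=s0)
    abs_obs = np.abs(t_obs)

    n = len(samples)
    assignments, exhaustive = _label_assignments(n, len(idx_a), n_perm, rng)
    all_idx = np.arange(n)
    null_abs = []
    for assign_a in assignments:
        assign_b = np.setdiff1d(all_idx, assign_a)
        t_perm, _ = t_statistics(values, assign_a, assign_b, s0=s0)
        null_abs.append(np.abs(t_perm))
    null_pool = np.concatenate(null_abs)
    null_pool = null_pool[np.isfinite(null_pool)]
    null_sorted = np.sort(null_pool)

    # empirical p: fraction of the pooled null >= observed |t|
    n_null = len(null_sorted)
    emp_p = 1.0 - np.searchsorted(null_sorted, abs_obs, side="left") / n_null
    sig = emp_p < alpha

    # FDR estimate at the implied threshold: median per-assignment call
    # count over the observed call count. The identity assignment and its
    # mirror reproduce the observed statistics exactly and are excluded
    # from the numerator (they stay in the pooled null).
    n_called = int(sig.sum())
    if n_called > 0:
        threshold = abs_obs[sig].min()
        ident = {frozenset(idx_a.tolist()), frozenset(idx_b.tolist())}
        perm_calls = [
            (na >= threshold).sum()
            for na, assign in zip(null_abs, assignments)
            if frozenset(assign.tolist()) not in ident
        ]
        fdr = float(np.median(perm_calls) / n_called) if perm_calls else 0.0
    else:
        fdr = 0.0

    index = matrix.data.index
    return PermutationResult(
        sig=pd.Series(sig, index=index),
        empirical_p=pd.Series(emp_p, index=index),
        n_assignments=len(assignments),
        exhaustive=exhaustive,
        fdr_estimate=fdr,
    )


def call_de(
    table: pd.DataFrame,
    log2_cut: float = 0.58,
    p_cut: float = 0.05,
    perm_sig: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the differential-expression thresholds.

    ``sig_p_fc`` = |delta| >= log2_cut (inclusive) and p < p_cut (strict);
    ``sig_fdr`` additionally requires the permutation flag when one is
    provided. Input needs 'delta' and 'p_value' columns.
    """
    out = table.copy()
    with np.errstate(invalid="ignore"):
        out["sig_p_fc"] = (out["delta"].abs() >= log2_cut) & (out["p_value"] < p_cut)
    out["sig_p_fc"] = out["sig_p_fc"].fillna(False).astype(bool)
    if perm_sig is not None:
        out["sig_fdr"] = out["sig_p_fc"] & perm_sig.reindex(out.index).fillna(False).astype(bool)
    else:
        out["sig_fdr"] = False
    return out


def exclusive_detection(
    lfq: QuantMatrix,
    design: SampleDesign,
    min_present: int | None = None,
) -> dict[str, list[str]]:
    """Proteins detected in one group's samples and in none of the other's.

    The strict rule requires detection in *all* samples of one group and
    zero in the other (the on/off pattern that ratio-based quantification
    cannot score because the ratio is undefined). ``min_present`` relaxes
    the 'all' side to at least that many samples.
    """
    result: dict[str, list[str]] = {g: [] for g in design.groups}
    present = lfq.mask
    for g_on, g_off in (design.groups, design.groups[::-1]):
        cols_on = [c for c in lfq.samples if design.group_of(c) == g_on]
        cols_off = [c for c in lfq.samples if design.group_of(c) == g_off]
        need = len(cols_on) if min_present is None else min_present
        n_on = present[cols_on].sum(axis=1)
        n_off = present[cols_off].sum(axis=1)
        hits = lfq.data.index[(n_on >= need) & (n_off == 0)]
        result[g_on] = list(hits)
    return result


def volcano_table(table: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (delta, -log10 p, significance) export; no recomputation."""
    if table.empty:
        return pd.DataFrame(columns=["delta", "neg_log10_p", "sig_p_fc", "sig_fdr"])
    out = pd.DataFrame(index=table.index)
    out["delta"] = table["delta"]
    out["neg_log10_p"] = -np.log10(table["p_value"])
    out["sig_p_fc"] = table.get("sig_p_fc", False)
    out["sig_fdr"] = table.get("sig_fdr", False)
    return out


class DifferentialExpression:
    """Two-group differential-expression model for a spike-in quant matrix.

    Parameters
    ----------
    matrix : QuantMatrix
        Biological-replicate-level log2 matrix (aggregate technical
        replicates first; see :func:`supersilac.quant.prepare_matrix`).
    design : SampleDesign
        Maps each matrix column to one of two groups. The reported log2
        difference is ``mean(group 2) - mean(group 1)`` in design order.
    impute : bool
        Whether to run the statistics on the downshift-imputed matrix
        (the unimputed arm is always computed as well, on proteins with
        >= 2 observed values per group).
    imputation : ImputationParams
        Downshift and width, in whole-matrix-SD units.
    log2_cut, p_cut : float
        Fold-change (inclusive) and p-value (strict) thresholds for the
        ``sig_p_fc`` call. Defaults: 0.58 (1.5-fold) and 0.05.
    fdr_alpha : float
        Level for the pooled permutation criterion behind ``sig_fdr``.
    n_perm : int
        Random label assignments when exhaustive enumeration is infeasible.
    s0 : float
        Optional variance-stabilizing constant added to the t denominator
        (0 = plain Student statistic).

    Examples
    --------
    >>> model = DifferentialExpression(matrix, design)
    >>> results = model.fit(seed=7)
    >>> results.table.head()
    >>> print(results.summary())
    """

    def __init__(
        self,
        matrix: QuantMatrix,
        design: SampleDesign,
        impute: bool = True,
        imputation: ImputationParams | None = None,
        log2_cut: float = 0.58,
        p_cut: float = 0.05,
        fdr_alpha: float = 0.05,
        n_perm: int = 250,
        s0: float = 0.0,
    ):
        unknown = [c for c in matrix.samples if c not in set(design.samples)]
        if unknown:
            raise ValueError(f"matrix columns not in design: {unknown}")
        self.matrix = matrix
        self.design = design
        self.impute = impute
        self.imputation = imputation or ImputationParams()
        self.log2_cut = log2_cut
        self.p_cut = p_cut
        self.fdr_alpha = fdr_alpha
        self.n_perm = n_perm
        self.s0 = s0

    @classmethod
    def from_protein_groups(
        cls,
        records,
        design: SampleDesign,
        standard_channel: str = "heavy",
        normalize: bool = True,
        min_valid: int = 2,
        scope: str | None = None,
        **kwargs,
    ) -> "DifferentialExpression":
        """Build the model straight from parsed protein-group records.

        Runs the full quantification preprocessing (log2, median-centering,
        technical-replicate medians, minimum-valid filter). The filter scope
        defaults to 'any' group when imputation is on and 'each' otherwise.
        """
        from .quant import prepare_matrix

        impute = kwargs.get("impute", True)
        if scope is None:
            scope = "any" if impute else "each"
        m, bdesign = prepare_matrix(
            records,
            design,
            standard_channel=standard_channel,
            normalize=normalize,
            min_valid=min_valid,
            scope=scope,  # type: ignore[arg-type]
        )
        return cls(m, bdesign, **kwargs)

    def fit(self, seed: int | np.random.Generator = 0) -> "DifferentialExpressionResults":
        """Run imputation, per-protein t-tests and the permutation background."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        a, b = self.design.groups
        samples = self.matrix.samples
        groups = [self.design.group_of(s) for s in samples]
        idx_a = np.array([i for i, g in enumerate(groups) if g == a])
        idx_b = np.array([i for i, g in enumerate(groups) if g == b])

        if self.impute:
            imputed_matrix, imputed_mask = impute_downshift(self.matrix, self.imputation, rng)
        else:
            imputed_matrix = self.matrix
            imputed_mask = pd.DataFrame(
                False, index=self.matrix.data.index, columns=self.matrix.data.columns
            )

        # --- primary arm: statistics on the (possibly imputed) matrix
        values = imputed_matrix.data.to_numpy()
        complete = np.isfinite(values).all(axis=1)
        t = np.full(len(values), np.nan)
        p = np.full(len(values), np.nan)
        t[complete], p[complete] = t_statistics(values[complete], idx_a, idx_b, s0=self.s0)

        # delta from observed values: imputation feeds the test statistic,
        # not the effect estimate. Only where a group has nothing observed
        # (an on/off pattern) do the imputed draws stand in for its mean.
        cols_a = [s for s in samples if self.design.group_of(s) == a]
        cols_b = [s for s in samples if self.design.group_of(s) == b]
        mean_a = self.matrix.data[cols_a].mean(axis=1, skipna=True)
        mean_b = self.matrix.data[cols_b].mean(axis=1, skipna=True)
        if self.impute:
            mean_a = mean_a.fillna(imputed_matrix.data[cols_a].mean(axis=1))
            mean_b = mean_b.fillna(imputed_matrix.data[cols_b].mean(axis=1))
        delta = mean_b - mean_a
        table = pd.DataFrame(index=imputed_matrix.data.index)
        table["delta"] = delta
        table["fold_change"] = np.power(2.0, delta)
        table["t_stat"] = t
        table["p_value"] = p
        # valid counts refer to actually observed (pre-imputation) values
        obs = self.matrix.mask
        table[f"n_valid_{a}"] = obs[cols_a].sum(axis=1)
        table[f"n_valid_{b}"] = obs[cols_b].sum(axis=1)
        table["n_imputed"] = imputed_mask.sum(axis=1)

        perm = None
        if complete.any():
            tested = QuantMatrix(imputed_matrix.data.loc[complete], imputed_matrix.source)
            perm = permutation_significance(
                tested,
                self.design,
                n_perm=self.n_perm,
                alpha=self.fdr_alpha,
                seed=rng,
                s0=self.s0,
            )
            table = call_de(table, self.log2_cut, self.p_cut, perm.sig)
        else:
            table = call_de(table, self.log2_cut, self.p_cut, None)

        # --- unimputed arm on observed values only (>= 2 per group)
        raw = self.matrix.data
        t_raw = np.full(len(raw), np.nan)
        p_raw = np.full(len(raw), np.nan)
        raw_np = raw.to_numpy()
        for i in range(len(raw)):
            va = raw_np[i, idx_a]
            vb = raw_np[i, idx_b]
            va = va[np.isfinite(va)]
            vb = vb[np.isfinite(vb)]
            if len(va) >= 2 and len(vb) >= 2:
                try:
                    t_raw[i], p_raw[i] = student_t(va, vb)
                except ValueError:  # zero pooled variance
                    pass
        table["t_stat_raw"] = t_raw
        table["p_value_raw"] = p_raw
        with np.errstate(invalid="ignore"):
            table["sig_p_fc_raw"] = (
                (table["delta"].abs() >= self.log2_cut) & (table["p_value_raw"] < self.p_cut)
            ).fillna(False).astype(bool)

        return DifferentialExpressionResults(self, table, imputed_matrix, imputed_mask, perm)


class DifferentialExpressionResults:
    """Fitted differential-expression results.

    Attributes
    ----------
    table : pandas.DataFrame
        Per-protein estimates: delta (log2 difference), fold_change
        (2**delta), t_stat, p_value, significance flags for both arms,
        per-group valid counts and imputation counts.
    permutation : PermutationResult or None
        Pooled-null diagnostics (empirical p values, FDR estimate).
    """

    def __init__(
        self,
        model: DifferentialExpression,
        table: pd.DataFrame,
        imputed_matrix: QuantMatrix,
        imputed_mask: pd.DataFrame,
        permutation: PermutationResult | None,
    ):
        self.model = model
        self.table = table
        self.imputed_matrix = imputed_matrix
        self.imputed_mask = imputed_mask
        self.permutation = permutation

    @property
    def n_tested(self) -> int:
        return int(self.table["p_value"].notna().sum())

    @property
    def n_sig_p_fc(self) -> int:
        return int(self.table["sig_p_fc"].sum())

    @property
    def n_sig_fdr(self) -> int:
        return int(self.table["sig_fdr"].sum())

    def de_proteins(self, flag: str = "sig_fdr") -> list[str]:
        return list(self.table.index[self.table[flag]])

    def top_table(self, n: int = 10, direction: str = "both") -> pd.DataFrame:
        """Most regulated significant proteins, Table-1 style (by |delta|)."""
        sig = self.table[self.table["sig_p_fc"]]
        if direction == "up":
            sig = sig[sig["delta"] > 0]
        elif direction == "down":
            sig = sig[sig["delta"] < 0]
        return sig.reindex(sig["delta"].abs().sort_values(ascending=False).index).head(n)

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.table)

    def plot_volcano(self, ax=None):
        """Volcano plot: log2 difference vs -log10 p, DE proteins highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        v = self.volcano_table().dropna(subset=["delta", "neg_log10_p"])
        bg = v[~v["sig_p_fc"]]
        fg = v[v["sig_p_fc"]]
        ax.scatter(bg["delta"], bg["neg_log10_p"], s=6, c="0.7", label="not significant")
        ax.scatter(fg["delta"], fg["neg_log10_p"], s=8, c="tab:blue", label="DE")
        ax.axhline(-np.log10(self.model.p_cut), ls=":", c="k", lw=0.8)
        for x in (-self.model.log2_cut, self.model.log2_cut):
            ax.axvline(x, ls=":", c="k", lw=0.8)
        ax.set_xlabel("log2 difference")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        """Plain-text overview of the fit."""
        m = self.model
        a, b = m.design.groups
        lines = [
            "Differential expression (two-group Student t, permutation background)",
            "=" * 68,
            f"groups:               {a} vs {b} "
            f"({m.design.n_bio(a)} vs {m.design.n_bio(b)} biological replicates)",
            f"proteins in matrix:   {m.matrix.shape[0]}",
            f"proteins tested:      {self.n_tested}",
            f"imputation:           {'on' if m.impute else 'off'} "
            f"(downshift {m.imputation.downshift} SD, width {m.imputation.width} SD)",
            f"thresholds:           |log2| >= {m.log2_cut}, p < {m.p_cut}, "
            f"permutation alpha {m.fdr_alpha}",
            f"significant (p & FC): {self.n_sig_p_fc}",
            f"significant (+ FDR):  {self.n_sig_fdr}",
        ]
        if self.permutation is not None:
            kind = "exhaustive" if self.permutation.exhaustive else "sampled"
            lines.append(
                f"permutation null:     {self.permutation.n_assignments} assignments "
                f"({kind}); estimated FDR at threshold {self.permutation.fdr_estimate:.3f}"
            )
        top = self.top_table(3)
        if len(top):
            lines.append("top regulated:        " + ", ".join(
                f"{prot} ({format_fold(row['delta'])}, p={row['p_value']:.2g})"
                for prot, row in top.iterrows()
            ))
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DifferentialExpressionResults {self.n_tested} tested, "
            f"{self.n_sig_p_fc} sig (p&FC), {self.n_sig_fdr} sig (FDR)>"
        )
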