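"""Rank-based annotation enrichment over per-protein expression differences.

For every annotation term, the log2 differences of member proteins are
compared with those of all other proteins by a two-sample Mann-Whitney U
test. The effect size reported is the rank-biserial score

    score = 2*U / (n_in * n_out) - 1,

bounded in [-1, 1], zero in expectation under exchangeability, positive
when the term's members rank above the background (up-regulated) and
negative when below. P-values come from exact enumeration for small terms
(n_in*n_out <= 400, no ties) and from the tie-corrected normal
approximation otherwise; Benjamini-Hochberg correction is applied across
all tested terms within a namespace.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

__all__ = [
    "rank_biserial_score",
    "annotation_enrichment",
    "compartment_fractions",
]

EXACT_LIMIT = 400


def rank_biserial_score(
    values_in: Sequence[float], values_out: Sequence[float]
) -> tuple[float, float]:
    """Rank-biserial enrichment score and two-sided Mann-Whitney p value.

    Positive score: in-term values tend to be larger than out-of-term
    values. Invariant under any strictly monotone transform of the values
    and antisymmetric under swapping the two sets.
    """
    x = np.asarray(values_in, dtype=float)
    y = np.asarray(values_out, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both value sets must be non-empty")
    n_in, n_out = len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n_in + n_out
    method = "exact" if (n_in * n_out <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_in = float(res.statistic)  # number of (in, out) pairs with in > out (+0.5 per tie)
    score = 2.0 * u_in / (n_in * n_out) - 1.0
    return score, float(res.pvalue)


def annotation_enrichment(
    deltas: Mapping[str, float] | pd.Series,
    annotations: AnnotationMap,
    min_term_size: int = 10,
    namespace: str | None = None,
) -> pd.DataFrame:
    """Score every qualifying annotation term against the value background.

    ``deltas`` maps protein accession -> expression value (typically the
    log2 group difference). A term qualifies when at least ``min_term_size``
    of its members have values. Returns one row per term with the in-term
    median (the 'median log2' statistic), rank-biserial score, p value and
    Benjamini-Hochberg FDR, sorted by p.
    """
    values = pd.Series(deltas, dtype=float).dropna()
    rows = []
    for term in annotations.terms(namespace):
        members = annotations.members[term] & set(values.index)
        if len(members) < min_term_size:
            continue
        in_mask = values.index.isin(members)
        v_in = values[in_mask].to_numpy()
        v_out = values[~in_mask].to_numpy()
        if len(v_out) == 0:
            continue
        score, p = rank_biserial_score(v_in, v_out)
        rows.append(
            {
                "term": term,
                "name": annotations.names.get(term, term),
                "n_in": len(v_in),
                "median_in": float(np.median(v_in)),
                "score": score,
                "p_value": p,
            }
        )
    if not rows:
        import warnings

        warnings.warn("no annotation term met min_term_size; empty enrichment result")
        return pd.DataFrame(
            columns=["term", "name", "n_in", "median_in", "score", "p_value", "fdr"]
        )
    result = pd.DataFrame(rows)
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def compartment_fractions(
    de_proteins: set[str] | Sequence[str],
    annotations: AnnotationMap,
    namespace: str | None = None,
) -> pd.Series:
    """Fraction of annotated DE proteins localized to each compartment.

    Denominator: DE proteins carrying at least one compartment annotation.
    Multi-localized proteins count once per compartment, so the fractions
    need not sum to 1.
    """
    de = set(de_proteins)
    if not de:
        raise ValueError("empty differential-expression set")
    terms = annotations.terms(namespace)
    annotated = de & set().union(*(annotations.members[t] for t in terms)) if terms else set()
    if not annotated:
        raise ValueError("no DE protein carries a compartment annotation")
    fractions = {
        t: len(de & annotations.members[t]) / len(annotated) for t in terms
    }
    return pd.Series(fractions, name="fraction").sort_values(ascending=False)
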