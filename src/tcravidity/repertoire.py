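"""Tracking predicted avidity labels in bulk repertoires and the %HA
enrichment permutation test.

A library of clonotypes with predicted high/low avidity labels is matched
into bulk blood and tumor beta-chain repertoires by exact CDR3b amino-acid
identity. The question is whether tumor-infiltrating clonotypes are enriched
in predicted high-avidity (HA) TCRs. Matched clonotypes are partitioned into
the n *infiltrating* TCRs (present in the tumor repertoire) and the m
*non-infiltrating* TCRs (present in blood only) — disjoint groups, so each
clonotype contributes one label. The test statistic is %HA_infiltrating -
%HA_non_infiltrating; its null distribution is built by relabeling: count
the F high-avidity clonotypes among the n + m, then independently redraw
each clonotype's label as HA with probability F/(n+m), recomputing the
statistic each of b times. (F is a count; dividing it by n + m gives the
pooled HA fraction used as the relabeling probability.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import RepertoireSample

#: clonotypes supported by a single read are excluded by default
DEFAULT_MIN_READS = 2


def label_repertoire(
    reference: Mapping[str, str],
    sample: RepertoireSample,
    min_reads: int = DEFAULT_MIN_READS,
) -> pd.DataFrame:
    """Attach predicted avidity labels to a bulk repertoire.

    ``reference`` maps CDR3b amino-acid sequence to "high" or "low"
    (typically the classifier's calls on a clonotype library). Matching is
    by exact CDR3b identity after upper-casing and whitespace stripping;
    unmatched rows are labeled "unknown" and excluded from percentage
    computations downstream. Clonotypes with fewer than ``min_reads`` reads
    are dropped (single-read clonotypes are unreliable and excluded by
    default).

    Returns the sample table with a ``label`` column plus match statistics
    in ``DataFrame.attrs`` (n_total, n_matched, match_fraction).
    """
    if not reference:
        raise ValueError("empty reference library")
    ref = {str(k).strip().upper(): v for k, v in reference.items()}
    bad = sorted(set(ref.values()) - {"high", "low"})
    if bad:
        raise ValueError(f"reference labels must be 'high'/'low', got {bad}")
    table = sample.table.copy()
    table = table[table["count"] >= min_reads].reset_index(drop=True)
    keys = table["cdr3_aa"].astype(str).str.strip().str.upper()
    table["label"] = [ref.get(k, "unknown") for k in keys]
    n_matched = int((table["label"] != "unknown").sum())
    table.attrs["n_total"] = len(table)
    table.attrs["n_matched"] = n_matched
    table.attrs["match_fraction"] = n_matched / len(table) if len(table) else float("nan")
    return table


def _partition_infiltrating(
    tumor: pd.DataFrame, blood: pd.DataFrame, weighted: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split matched clonotypes into disjoint infiltrating / non-infiltrating
    groups and return (HA indicator, weight) arrays for each.

    Infiltrating = matched in the tumor repertoire; non-infiltrating =
    matched in blood only. A clonotype found in both compartments counts once,
    as infiltrating. Weights are read counts when ``weighted`` (tumor counts
    for infiltrating clonotypes, blood counts otherwise) and 1 per clonotype
    by default.
    """

    def matched_map(table: pd.DataFrame) -> dict[str, tuple[bool, int]]:
        out: dict[str, tuple[bool, int]] = {}
        for _, row in table[table["label"] != "unknown"].iterrows():
            key = str(row["cdr3_aa"]).strip().upper()
            prev = out.get(key)
            count = int(row["count"]) + (prev[1] if prev else 0)
            out[key] = (row["label"] == "high", count)
        return out

    tumor_map = matched_map(tumor)
    blood_map = matched_map(blood)
    inf_keys = sorted(tumor_map)
    non_keys = sorted(set(blood_map) - set(tumor_map))
    ha_inf = np.array([tumor_map[k][0] for k in inf_keys], dtype=bool)
    ha_non = np.array([blood_map[k][0] for k in non_keys], dtype=bool)
    if weighted:
        w_inf = np.array([tumor_map[k][1] for k in inf_keys], dtype=float)
        w_non = np.array([blood_map[k][1] for k in non_keys], dtype=float)
    else:
        w_inf = np.ones(len(inf_keys))
        w_non = np.ones(len(non_keys))
    return ha_inf, w_inf, ha_non, w_non


@dataclass
class EnrichmentResult:
    """Outcome of the %HA infiltrating-vs-non-infiltrating relabeling test."""

    n_infiltrating: int
    n_non_infiltrating: int
    pct_ha_infiltrating: float
    pct_ha_non_infiltrating: float
    observed: float  # %HA_infiltrating - %HA_non_infiltrating
    b: int
    p_value: float

    def summary(self) -> str:
        return (
            f"%HA infiltrating {self.pct_ha_infiltrating:.1f}% "
            f"(n={self.n_infiltrating}) vs non-infiltrating "
            f"{self.pct_ha_non_infiltrating:.1f}% (m={self.n_non_infiltrating}); "
            f"difference {self.observed:+.1f} points, P = {self.p_value:.4g} "
            f"({self.b} relabeling replicates)"
        )


def _relabeling_pvalue(
    ha_inf: np.ndarray,
    w_inf: np.ndarray,
    ha_non: np.ndarray,
    w_non: np.ndarray,
    b: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, np.ndarray, float]:
    """Shared core: observed statistic, replicate distribution, add-one p."""
    n, m = len(ha_inf), len(ha_non)
    pct_inf = 100.0 * float(w_inf @ ha_inf) / float(w_inf.sum())
    pct_non = 100.0 * float(w_non @ ha_non) / float(w_non.sum())
    observed = pct_inf - pct_non
    # F is the COUNT of HA clonotypes among the n + m; F/(n+m) is the pooled
    # HA fraction used as the per-clonotype relabeling probability.
    prob = (int(ha_inf.sum()) + int(ha_non.sum())) / (n + m)
    draws = rng.random((b, n + m)) < prob
    rep_inf = 100.0 * (draws[:, :n] @ w_inf) / w_inf.sum()
    rep_non = 100.0 * (draws[:, n:] @ w_non) / w_non.sum()
    rep_stat = rep_inf - rep_non
    p = (1.0 + np.sum(rep_stat >= observed - 1e-12)) / (b + 1.0)
    return pct_inf, pct_non, observed, rep_stat, float(p)


def ha_enrichment_test(
    tumor: pd.DataFrame,
    blood: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    weighted: bool = False,
    return_distribution: bool = False,
):
    """Randomisation test for HA enrichment among tumor-infiltrating clonotypes.

    ``tumor`` and ``blood`` are labeled tables from :func:`label_repertoire`
    ("unknown" rows are ignored). Matched clonotypes are partitioned into the
    n infiltrating (present in tumor) and m non-infiltrating (blood only).
    Percentages are over unique clonotypes by default; ``weighted=True``
    weights them by read count instead (the two agree when all counts are
    equal). The p-value uses the add-one convention
    (1 + #{replicate >= observed}) / (b + 1), one-sided for tumor enrichment,
    so it is never exactly zero.
    """
    if b < 1:
        raise ValueError("need at least one relabeling replicate")
    ha_inf, w_inf, ha_non, w_non = _partition_infiltrating(tumor, blood, weighted)
    n, m = len(ha_inf), len(ha_non)
    if n == 0 or m == 0:
        raise ValueError(
            "need matched clonotypes in both groups (tumor-infiltrating and blood-only)"
        )
    if n + m < 2:
        raise ValueError("need at least two matched clonotypes across compartments")
    rng = np.random.default_rng(seed)
    pct_inf, pct_non, observed, rep_stat, p = _relabeling_pvalue(
        ha_inf, w_inf, ha_non, w_non, b, rng
    )
    result = EnrichmentResult(
        n_infiltrating=n,
        n_non_infiltrating=m,
        pct_ha_infiltrating=pct_inf,
        pct_ha_non_infiltrating=pct_non,
        observed=observed,
        b=b,
        p_value=p,
    )
    if return_distribution:
        return result, rep_stat
    return result


def combined_ha_enrichment_test(
    pairs: Sequence[tuple[pd.DataFrame, pd.DataFrame]],
    b: int = 1000,
    seed: int = 0,
    weighted: bool = False,
) -> EnrichmentResult:
    """Cumulative test over several patients.

    Each patient keeps their own pooled HA fraction F_p/(n_p + m_p) as the
    relabeling probability; the statistic is the %HA difference computed over
    all patients' clonotypes pooled together (infiltrating vs
    non-infiltrating, each patient's groups disjoint as in the single-patient
    test).
    """
    if b < 1:
        raise ValueError("need at least one relabeling replicate")
    rng = np.random.default_rng(seed)
    parts = []
    for tumor, blood in pairs:
        ha_inf, w_inf, ha_non, w_non = _partition_infiltrating(tumor, blood, weighted)
        if len(ha_inf) == 0 or len(ha_non) == 0:
            raise ValueError(
                "each patient needs clonotypes in both groups "
                "(tumor-infiltrating and blood-only)"
            )
        parts.append((ha_inf, w_inf, ha_non, w_non))
    w_inf_tot = sum(float(p[1].sum()) for p in parts)
    w_non_tot = sum(float(p[3].sum()) for p in parts)
    pct_inf = 100.0 * sum(float(p[1] @ p[0]) for p in parts) / w_inf_tot
    pct_non = 100.0 * sum(float(p[3] @ p[2]) for p in parts) / w_non_tot
    observed = pct_inf - pct_non
    rep_inf = np.zeros(b)
    rep_non = np.zeros(b)
    for ha_inf, w_inf, ha_non, w_non in parts:
        n, m = len(ha_inf), len(ha_non)
        prob = (int(ha_inf.sum()) + int(ha_non.sum())) / (n + m)
        draws = rng.random((b, n + m)) < prob
        rep_inf += draws[:, :n] @ w_inf
        rep_non += draws[:, n:] @ w_non
    rep_stat = 100.0 * (rep_inf / w_inf_tot - rep_non / w_non_tot)
    p = (1.0 + np.sum(rep_stat >= observed - 1e-12)) / (b + 1.0)
    return EnrichmentResult(
        n_infiltrating=sum(len(p[0]) for p in parts),
        n_non_infiltrating=sum(len(p[2]) for p in parts),
        pct_ha_infiltrating=pct_inf,
        pct_ha_non_infiltrating=pct_non,
        observed=observed,
        b=b,
        p_value=float(p),
    )
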