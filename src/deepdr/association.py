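"""Downstream pharmacogenomic statistics on predicted drug responses.

Two analyses operate on a predicted drug x sample log-IC50 matrix:

* a mutation-drug scan — per stratum (e.g. cancer type) or pan-cohort — that
  Welch-t-tests predicted IC50 between mutation carriers and wildtype samples
  for every admissible (stratum, gene, drug) triple, with Bonferroni control
  over all tests in the scan (delta IC50 > 0 marks a resistance-associated
  mutation, < 0 a sensitizing one);
* an extreme-responder characterization for one drug: the bottom and top
  fraction of predicted IC50 define sensitive and resistant groups, compared
  by stratum composition, per-gene mutation-rate differences, and a ranked
  differential-expression table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

SCAN_COLUMNS = [
    "stratum",
    "gene",
    "drug",
    "delta_ic50",
    "t_stat",
    "p_raw",
    "p_adj",
    "n_mut",
    "n_wt",
    "direction",
    "significant",
]


@dataclass(frozen=True)
class ScanFilter:
    """Admissibility filters and significance threshold for the scan.

    min_mutation_rate: strict lower bound on the within-stratum mutation rate.
    min_carriers: minimum carrier count (enforced in stratified scans only).
    alpha_adjusted: Bonferroni-adjusted significance threshold.
    """

    min_mutation_rate: float = 0.10
    min_carriers: int = 10
    alpha_adjusted: float = 1.0e-5

    def __post_init__(self) -> None:
        if not 0 < self.min_mutation_rate < 1:
            raise ValidationError("min_mutation_rate must be in (0, 1)")
        if self.min_carriers < 0:
            raise ValidationError("min_carriers must be >= 0")
        if self.alpha_adjusted <= 0:
            raise ValidationError("alpha_adjusted must be > 0")


def mutation_drug_scan(
    pred_ic: pd.DataFrame,
    M: pd.DataFrame,
    strata: pd.DataFrame | None = None,
    filt: ScanFilter | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Scan all admissible (stratum, gene, drug) triples for response shifts.

    ``pred_ic`` is drug x sample, ``M`` gene x sample binary; ``strata`` a
    sample annotation with a ``stratum`` column, or None for a pan-cohort
    scan. For each admissible (stratum, gene) — mutation rate strictly above
    ``filt.min_mutation_rate``, and in stratified mode at least
    ``filt.min_carriers`` carriers — every drug is tested by a two-tailed
    Welch t-test (``equal_var=True`` for the pooled variant). Raw P values
    are Bonferroni-multiplied by the total number of tests in this scan,
    capped at 1.

    Returns a DataFrame with one row per test (columns ``SCAN_COLUMNS``),
    including non-significant tests; filter on ``significant`` for the hits.
    """
    filt = filt or ScanFilter()
    if list(pred_ic.columns) != list(M.columns):
        if set(pred_ic.columns) != set(M.columns):
            raise ValidationError("pred_ic and M sample ids differ")
        M = M.loc[:, pred_ic.columns]

    if strata is None:
        groups = [("pan", list(pred_ic.columns))]
    else:
        missing = set(pred_ic.columns) - set(strata.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} samples lack stratum labels (e.g. {sorted(missing)[:5]})"
            )
        labels = strata.loc[list(pred_ic.columns), "stratum"]
        groups = [(str(k), list(v.index)) for k, v in labels.groupby(labels)]

    rows = []
    skipped = 0
    for stratum, samples in groups:
        ic_s = pred_ic.loc[:, samples].to_numpy(dtype=float)
        m_s = M.loc[:, samples].to_numpy()
        n = len(samples)
        rates = m_s.sum(axis=1) / n
        admissible = rates > filt.min_mutation_rate
        if strata is not None:
            admissible &= m_s.sum(axis=1) >= filt.min_carriers
        for g in np.flatnonzero(admissible):
            carrier = m_s[g] == 1
            n_mut, n_wt = int(carrier.sum()), int((~carrier).sum())
            if n_mut < 2 or n_wt < 2:
                skipped += 1
                logger.warning(
                    "skipping gene %s in stratum %s: group sizes (%d, %d) too small",
                    M.index[g], stratum, n_mut, n_wt,
                )
                continue
            mut_vals = ic_s[:, carrier]
            wt_vals = ic_s[:, ~carrier]
            t_stat, p_raw = stats.ttest_ind(
                mut_vals, wt_vals, axis=1, equal_var=equal_var
            )
            delta = mut_vals.mean(axis=1) - wt_vals.mean(axis=1)
            for d in range(pred_ic.shape[0]):
                rows.append(
                    (stratum, M.index[g], pred_ic.index[d], float(delta[d]),
                     float(t_stat[d]), float(p_raw[d]), n_mut, n_wt)
                )
    records = pd.DataFrame(
        rows,
        columns=["stratum", "gene", "drug", "delta_ic50", "t_stat", "p_raw", "n_mut", "n_wt"],
    )
    n_tests = len(records)
    records["p_adj"] = np.minimum(records["p_raw"] * n_tests, 1.0) if n_tests else []
    records["direction"] = np.where(records["delta_ic50"] > 0, "resistant", "sensitive")
    records["significant"] = records["p_adj"] < filt.alpha_adjusted
    return records[SCAN_COLUMNS]


def direction_shares(records: pd.DataFrame, significant_only: bool = True) -> pd.Series:
    """Percent of records per response direction (sums to 100).

    With ``significant_only`` (default) only records flagged significant are
    counted, reproducing the resistant/sensitive share summary of a scan.
    """
    if significant_only and "significant" in records.columns:
        records = records[records["significant"]]
    if len(records) == 0:
        raise ValidationError("no records to summarize")
    counts = records["direction"].value_counts()
    return 100.0 * counts / counts.sum()


def extreme_responder_groups(
    pred_row: pd.Series, fraction: float = 0.01
) -> tuple[list[str], list[str]]:
    """Bottom/top ``fraction`` of samples by one drug's predicted IC50.

    Group size is ceil(fraction * n). Returns (sensitive, resistant) sample-id
    lists; ties are broken by stable sample order. Raises if the groups would
    overlap.
    """
    if not 0 < fraction < 0.5:
        raise ValidationError("fraction must be in (0, 0.5)")
    n = len(pred_row)
    size = math.ceil(fraction * n)
    if 2 * size > n:
        raise ValidationError(
            f"groups of {size} would overlap in a cohort of {n} samples"
        )
    values = pred_row.to_numpy(dtype=float)
    order = np.argsort(values, kind="stable")
    sensitive = [str(pred_row.index[i]) for i in order[:size]]
    resistant = [str(pred_row.index[i]) for i in order[-size:]]
    return sensitive, resistant


@dataclass
class ExtremeResponderReport:
    """Drug-centric comparison of the sensitive vs resistant extremes."""

    drug: str
    sensitive: list[str]
    resistant: list[str]
    composition: pd.DataFrame = field(repr=False)  # stratum x {sensitive, resistant}, percent
    mutation_rates: pd.DataFrame = field(repr=False)  # per-gene rates + difference, ranked
    diff_expression: pd.DataFrame = field(repr=False)  # per-gene Welch t results, ranked
    top_expr_genes: list[str] = field(default_factory=list)
    top_mut_genes: list[str] = field(default_factory=list)


def group_characterization(
    groups: tuple[list[str], list[str]],
    M: pd.DataFrame,
    E: pd.DataFrame,
    strata: pd.DataFrame,
    top_n_expr: int = 300,
    top_n_mut: int = 10,
    drug: str = "",
) -> ExtremeResponderReport:
    """Characterize extreme-responder groups for one drug.

    Computes, between the sensitive and resistant sample sets: percent stratum
    composition per group; per-gene mutation-rate differences (sensitive −
    resistant) ranked by absolute difference with the top ``top_n_mut``
    reported; and per-gene Welch t-tests on expression ranked by raw P (ties
    by |t|), with the top ``top_n_expr`` gene ids and their direction
    (up/down in sensitive) reported.
    """
    sensitive, resistant = [list(g) for g in groups]
    if not sensitive or not resistant:
        raise ValidationError("both groups must be non-empty")
    if set(sensitive) & set(resistant):
        raise ValidationError("groups overlap")

    comp = {}
    for name, members in (("sensitive", sensitive), ("resistant", resistant)):
        labels = strata.loc[members, "stratum"]
        comp[name] = 100.0 * labels.value_counts() / len(members)
    composition = pd.DataFrame(comp).fillna(0.0)
    composition.index.name = "stratum"

    rate_s = M.loc[:, sensitive].mean(axis=1)
    rate_r = M.loc[:, resistant].mean(axis=1)
    mutation_rates = pd.DataFrame(
        {"rate_sensitive": rate_s, "rate_resistant": rate_r, "difference": rate_s - rate_r}
    )
    mutation_rates["abs_difference"] = mutation_rates["difference"].abs()
    mutation_rates = mutation_rates.sort_values(
        "abs_difference", ascending=False, kind="stable"
    ).drop(columns="abs_difference")

    Xs = E.loc[:, sensitive].to_numpy(dtype=float)
    Xr = E.loc[:, resistant].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_raw = stats.ttest_ind(Xs, Xr, axis=1, equal_var=False)
    diff = Xs.mean(axis=1) - Xr.mean(axis=1)
    de = pd.DataFrame(
        {
            "t_stat": t_stat,
            "p_raw": p_raw,
            "mean_difference": diff,
            "direction": np.where(diff > 0, "up_in_sensitive", "down_in_sensitive"),
        },
        index=E.index,
    )
    de["_abs_t"] = de["t_stat"].abs()
    de = de.sort_values(["p_raw", "_abs_t"], ascending=[True, False], kind="stable").drop(
        columns="_abs_t"
    )

    return ExtremeResponderReport(
        drug=drug,
        sensitive=sensitive,
        resistant=resistant,
        composition=composition,
        mutation_rates=mutation_rates,
        diff_expression=de,
        top_expr_genes=de.index[: min(top_n_expr, len(de))].tolist(),
        top_mut_genes=mutation_rates.index[: min(top_n_mut, len(mutation_rates))].tolist(),
    )


def mean_mutation_burden(group: list[str], M: pd.DataFrame, gene_subset: list[str]) -> float:
    """Mean per-sample count of mutated genes within ``gene_subset``."""
    if not group:
        raise ValidationError("group is empty")
    if not gene_subset:
        raise ValidationError("gene_subset is empty")
    return float(M.loc[list(gene_subset), list(group)].sum(axis=0).mean())
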