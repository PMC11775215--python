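"""Efficiency-corrected relative expression (Pfaffl-style) and group tests.

The workflow mirrors the standard crispant-vs-control qPCR analysis: per
sample, the reference-gene Ct is subtracted from the gene of interest
(ΔCt); the calibrator is the mean ΔCt of the pooled control samples
(wild-type and albino groups together); ΔΔCt = ΔCt − calibrator; and the
fold change uses the measured per-gene amplification efficiency E (fold
per cycle, near 2 for a good assay) instead of assuming perfect doubling:

    single_efficiency (default):  FC = E_goi ** (−ΔΔCt)
    pfaffl_full:                  FC = E_goi ** (Ct_goi,cal − Ct_goi,sample)
                                     / E_ref ** (Ct_ref,cal − Ct_ref,sample)

The two modes coincide whenever E_goi == E_ref.  Group comparisons use
the Mann–Whitney U test with an exact permutation p-value for small
tie-free samples and a tie- and continuity-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_EFFICIENCIES",
    "efficiency_table",
    "collapse_replicates",
    "fold_change",
    "mann_whitney",
    "group_comparison",
    "CONTROL_GROUPS",
]

CONTROL_GROUPS = ("control_wt", "control_albino")

#: Measured amplification efficiencies (fold per cycle) by gene and tissue
#: for the salmon immunoglobulin assays and the Ef1a reference gene.
DEFAULT_EFFICIENCIES: dict[tuple[str, str], float] = {
    ("Ef1a", "head_kidney"): 2.05,
    ("Ef1a", "spleen"): 2.09,
    ("sIgM", "head_kidney"): 2.05,
    ("sIgM", "spleen"): 2.02,
    ("mIgM", "head_kidney"): 2.06,
    ("mIgM", "spleen"): 2.05,
    ("IgT", "head_kidney"): 2.04,
    ("IgT", "spleen"): 2.02,
}


def efficiency_table(mapping: dict[tuple[str, str], float] | None = None) -> pd.DataFrame:
    """Efficiencies as a tidy frame (gene, tissue, efficiency)."""
    mapping = DEFAULT_EFFICIENCIES if mapping is None else mapping
    for (gene, tissue), e in mapping.items():
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency for {gene}/{tissue} out of range (1, 2.2]: {e}")
    return pd.DataFrame(
        [{"gene": g, "tissue": t, "efficiency": e} for (g, t), e in mapping.items()]
    )


def collapse_replicates(
    ct_replicates, sd_threshold: float = 0.5
) -> tuple[float, float, bool]:
    """Mean Ct over technical replicates, with an SD quality flag.

    Returns (mean, sd, high_sd_flag); sd is 0 for a single replicate.
    NaN replicates are dropped; all-missing is an error.
    """
    values = np.asarray([c for c in ct_replicates if np.isfinite(c)], dtype=float)
    if values.size == 0:
        raise ValueError("no finite Ct replicates")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd, sd > sd_threshold


def _collapse_frame(records: pd.DataFrame) -> pd.DataFrame:
    rep_cols = [c for c in records.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("Ct table needs at least one ct_rep* column")
    out = records.copy()
    collapsed = out[rep_cols].apply(
        lambda row: collapse_replicates(row.values), axis=1, result_type="expand"
    )
    out["ct"] = collapsed[0]
    out["ct_sd"] = collapsed[1]
    out["high_sd"] = collapsed[2]
    return out


def fold_change(
    records: pd.DataFrame,
    efficiencies: pd.DataFrame | dict | None = None,
    mode: str = "single_efficiency",
    reference_gene: str = "Ef1a",
    control_groups: tuple[str, ...] = CONTROL_GROUPS,
) -> pd.DataFrame:
    """Per sample×gene×tissue efficiency-corrected fold changes.

    ``records`` is long-format with columns sample_id, group, tissue,
    gene and ct_rep1..ct_repN.  The calibrator per (gene, tissue) is the
    mean control ΔCt with both control groups pooled.
    """
    if mode not in ("single_efficiency", "pfaffl_full"):
        raise ValueError(f"unknown mode {mode!r}")
    required = {"sample_id", "group", "tissue", "gene"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns: {sorted(missing)}")
    if isinstance(efficiencies, dict) or efficiencies is None:
        efficiencies = efficiency_table(efficiencies)
    eff = {(r.gene, r.tissue): r.efficiency for r in efficiencies.itertuples()}

    df = _collapse_frame(records)
    ref = df[df["gene"] == reference_gene].set_index(["sample_id", "tissue"])["ct"]
    goi = df[df["gene"] != reference_gene].copy()
    if goi.empty:
        raise ValueError("no gene-of-interest rows in the Ct table")
    key = list(zip(goi["sample_id"], goi["tissue"]))
    missing_ref = [k for k in key if k not in ref.index]
    if missing_ref:
        raise ValueError(
            f"missing reference gene {reference_gene!r} for sample/tissue: "
            f"{sorted(set(missing_ref))}"
        )
    goi["ct_ref"] = [ref.loc[k] for k in key]
    goi = goi.rename(columns={"ct": "ct_goi"})
    goi["delta_ct"] = goi["ct_goi"] - goi["ct_ref"]

    out_rows = []
    for (gene, tissue), sub in goi.groupby(["gene", "tissue"], sort=False):
        if (gene, tissue) not in eff:
            raise ValueError(f"missing efficiency for gene {gene!r} in tissue {tissue!r}")
        e_goi = eff[(gene, tissue)]
        controls = sub[sub["group"].isin(control_groups)]
        if controls.empty:
            raise ValueError(f"no control samples for {gene}/{tissue}")
        calibrator = controls["delta_ct"].mean()
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - calibrator
        if mode == "single_efficiency":
            sub["fold_change"] = e_goi ** (-sub["delta_delta_ct"])
        else:
            if (reference_gene, tissue) not in eff:
                raise ValueError(
                    f"missing efficiency for reference gene {reference_gene!r} "
                    f"in tissue {tissue!r}"
                )
            e_ref = eff[(reference_gene, tissue)]
            cal_ct_goi = controls["ct_goi"].mean()
            cal_ct_ref = controls["ct_ref"].mean()
            sub["fold_change"] = (e_goi ** (cal_ct_goi - sub["ct_goi"])) / (
                e_ref ** (cal_ct_ref - sub["ct_ref"])
            )
        out_rows.append(
            sub[
                [
                    "sample_id",
                    "group",
                    "tissue",
                    "gene",
                    "ct_goi",
                    "ct_ref",
                    "delta_ct",
                    "delta_delta_ct",
                    "fold_change",
                ]
            ]
        )
    return pd.concat(out_rows, ignore_index=True)


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    diff = a[:, None] - b[None, :]
    u_a = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    return u_a, len(a) * len(b) - u_a


@lru_cache(maxsize=64)
def _exact_u_counts(n_a: int, n_b: int) -> tuple[int, ...]:
    """Null distribution of U_a for tie-free samples, by count recurrence.

    ``counts[u]`` is the number of the C(n_a+n_b, n_a) equally likely group
    assignments with U_a == u — an exact enumeration of the permutation
    distribution, computed by the classical recursion
    f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u).
    """
    max_u = n_a * n_b
    prev = [[0] * (max_u + 1) for _ in range(n_b + 1)]
    for n in range(n_b + 1):
        prev[n][0] = 1  # m = 0
    for m in range(1, n_a + 1):
        cur = [[0] * (max_u + 1) for _ in range(n_b + 1)]
        cur[0][0] = 1
        for n in range(1, n_b + 1):
            for u in range(max_u + 1):
                v = prev[n][u - n] if u >= n else 0
                cur[n][u] = v + cur[n - 1][u]
        prev = cur
    return tuple(prev[n_b])


def mann_whitney(group_a, group_b, exact_limit: int = 16) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided.

    Returns (U, p) with U = min(U_a, U_b).  The p-value is the exact
    permutation probability P(min(U_a, U_b) <= observed) when the pooled
    sample has no ties and at most ``exact_limit`` observations; otherwise
    a normal approximation with tie correction and a continuity
    correction (|U − μ| reduced by 1/2, clamped at 0, so identical groups
    give p = 1).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_a, u_b = _u_statistics(a, b)
    u = min(u_a, u_b)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    n_a, n_b = len(a), len(b)
    if no_ties and n_a + n_b <= exact_limit:
        counts = _exact_u_counts(n_a, n_b)
        max_u = n_a * n_b
        u_int = int(round(u))
        hits = sum(c for v, c in enumerate(counts) if min(v, max_u - v) <= u_int)
        return u, hits / comb(n_a + n_b, n_a)
    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = max(abs(u - mu) - 0.5, 0.0) / sqrt(var)
    return u, float(min(1.0, 2.0 * norm.sf(z)))


def exact_mann_whitney_enumeration(group_a, group_b) -> float:
    """Brute-force two-sided exact p by explicit assignment enumeration.

    Kept as an independent cross-check of the recurrence-based exact path;
    only sensible for small samples.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    u_obs = min(_u_statistics(a, b))
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)
    hits = 0
    total = 0
    idx = set(range(n))
    for pick in combinations(range(n), n_a):
        rest = tuple(idx - set(pick))
        u = min(_u_statistics(pooled[list(pick)], pooled[list(rest)]))
        hits += u <= u_obs + 1e-12
        total += 1
    return hits / total


def group_comparison(
    expression: pd.DataFrame,
    control_groups: tuple[str, ...] = CONTROL_GROUPS,
    test_group: str = "crispant",
) -> pd.DataFrame:
    """Per gene×tissue Mann–Whitney comparison of fold changes.

    Controls are pooled, mirroring the calibrator convention.  Reports U,
    the two-sided p, and the group medians.
    """
    rows = []
    for (gene, tissue), sub in expression.groupby(["gene", "tissue"], sort=False):
        fc_test = sub.loc[sub["group"] == test_group, "fold_change"].to_numpy()
        fc_ctrl = sub.loc[sub["group"].isin(control_groups), "fold_change"].to_numpy()
        if fc_test.size == 0 or fc_ctrl.size == 0:
            raise ValueError(f"missing a group for {gene}/{tissue}")
        u, p = mann_whitney(fc_test, fc_ctrl)
        rows.append(
            {
                "gene": gene,
                "tissue": tissue,
                "n_test": fc_test.size,
                "n_control": fc_ctrl.size,
                "median_fc_test": float(np.median(fc_test)),
                "median_fc_control": float(np.median(fc_ctrl)),
                "U": u,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
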