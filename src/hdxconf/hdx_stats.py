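"""Replicate summaries, the hybrid two-stage significance test, and
residue-level projection of peptide differences.

The two-stage test screens per-peptide uptake differences between two
conditions without any model fitting.  Stage 1 is a per-exposure gate: the
peptide's average SEM is scaled by the two-sided Student-t quantile at
confidence ``ci1`` (df = replicates − 1) to give a test value; a labeled
exposure is significant when its |ΔD| reaches that value, and the peptide
advances only when significant exposures form a strict majority (3 of 4 at
the standard design).  Stage 2 gates the summed difference: |Σ ΔD| must
reach ``summed SEM × t(ci2, df = exposures − 1)`` with the summed SEM
taken as average SEM × number of labeled exposures.  A peptide is called
significant only when both gates pass; the two gates compound, which keeps
the realised false-positive rate well below the nominal levels.

Two SEM pooling conventions are provided, because the published wording is
ambiguous about how the two conditions' SEMs combine: ``"quadrature"``
(default) uses the SEM of the difference, √(SEM_A² + SEM_B²) per exposure,
averaged over exposures; ``"literal-average"`` averages all per-condition
SEMs across exposures and conditions.  Outputs record the mode used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hdx_io import PEPTIDE_KEY, UptakeTable

__all__ = [
    "summarize",
    "two_stage_test",
    "DifferentialResult",
    "residue_level_map",
    "coverage_metrics",
]


def summarize(table: UptakeTable, value: str = "uptake") -> pd.DataFrame:
    """Per (peptide, state, exposure) mean, SD (n−1), SEM = SD/√n, and n.

    Entries with fewer than two replicates are excluded and noted in the
    table's audit log.
    """
    if value not in table.data.columns:
        raise ValueError(f"column {value!r} missing; run uptake_from_centroids first")
    key = PEPTIDE_KEY + ["state", "exposure"]
    g = table.data.groupby(key)[value]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    too_few = out["n"] < 2
    if too_few.any():
        table.note("summarize", excluded_entries=int(too_few.sum()),
                   reason="fewer than 2 replicates")
    out = out[~too_few].reset_index(drop=True)
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


@dataclass
class DifferentialResult:
    """Outcome of the two-stage test.

    ``peptides`` has one row per peptide with the summed difference, both
    test values and verdicts; ``exposures`` is the long per-exposure table
    with ΔD and stage-1 flags; ``params`` records the configuration.
    """

    peptides: pd.DataFrame
    exposures: pd.DataFrame
    params: dict = field(default_factory=dict)
    audit: list = field(default_factory=list)

    @property
    def n_significant(self) -> int:
        return int(self.peptides["significant"].sum())


def two_stage_test(summary_a: pd.DataFrame, summary_b: pd.DataFrame,
                   ci1: float = 0.95, ci2: float = 0.99,
                   pooling: str = "quadrature",
                   df_stage2: int | None = None) -> DifferentialResult:
    """Two-stage significance test on uptake differences (B − A).

    Parameters
    ----------
    summary_a, summary_b
        Outputs of :func:`summarize` restricted to one state each.
    ci1, ci2
        Two-sided confidence levels of stage 1 and stage 2.
    pooling
        ``"quadrature"`` or ``"literal-average"`` (see module docstring).
    df_stage2
        Override for stage 2 degrees of freedom; defaults to
        ``n_labeled_exposures − 1``.

    Only labeled exposures (t > 0) enter either stage.  Ties at a
    threshold count as significant.  Differences are in Da.
    """
    if pooling not in ("quadrature", "literal-average"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    for name, s in (("summary_a", summary_a), ("summary_b", summary_b)):
        if s["state"].nunique() > 1:
            raise ValueError(f"{name} contains multiple states: {sorted(s['state'].unique())}")

    key = PEPTIDE_KEY + ["exposure"]
    a = summary_a[summary_a["exposure"] > 0]
    b = summary_b[summary_b["exposure"] > 0]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="outer", indicator=True)
    audit = []
    unmatched = merged["_merge"] != "both"
    if unmatched.any():
        lost = merged.loc[unmatched, PEPTIDE_KEY].drop_duplicates()
        # a peptide partially present would silently change its exposure
        # count; that is a design violation, so reject loudly
        partial = merged[merged[PEPTIDE_KEY].apply(tuple, axis=1)
                         .isin(lost.apply(tuple, axis=1))]
        fully_missing = (partial.groupby(PEPTIDE_KEY)["_merge"]
                         .apply(lambda s: (s != "both").all()))
        bad = fully_missing[~fully_missing].index.tolist()
        if bad:
            raise ValueError(f"mismatched exposures between conditions for peptides: {bad[:5]}")
        for rec in lost.to_dict("records"):
            audit.append({**rec, "excluded": True,
                          "reason": "peptide absent from one condition"})
        merged = merged[~merged[PEPTIDE_KEY].apply(tuple, axis=1)
                        .isin(lost.apply(tuple, axis=1))]
    merged = merged.drop(columns="_merge")
    if merged.empty:
        empty = pd.DataFrame(columns=PEPTIDE_KEY + ["significant"])
        return DifferentialResult(empty, merged, {"pooling": pooling}, audit)

    merged["dD"] = merged["mean_b"] - merged["mean_a"]
    merged["sem_diff"] = np.sqrt(merged["sem_a"] ** 2 + merged["sem_b"] ** 2)
    merged["n_min"] = merged[["n_a", "n_b"]].min(axis=1)

    def per_peptide(grp: pd.DataFrame) -> pd.Series:
        n_exp = len(grp)
        df1 = int(grp["n_min"].min()) - 1
        if df1 <= 0:
            raise ValueError("need at least 2 replicates per condition (df <= 0)")
        if pooling == "quadrature":
            avg_sem = grp["sem_diff"].mean()
        else:
            avg_sem = (grp["sem_a"].sum() + grp["sem_b"].sum()) / n_exp
        t1 = stats.t.ppf(1 - (1 - ci1) / 2, df1)
        test1 = avg_sem * t1
        n_sig = int((grp["dD"].abs() >= test1).sum())
        stage1 = n_sig > n_exp / 2  # strict majority; 3 of 4 at the standard design
        sum_dd = grp["dD"].sum()
        summed_sem = avg_sem * n_exp
        df2 = df_stage2 if df_stage2 is not None else n_exp - 1
        if df2 <= 0:
            raise ValueError("stage 2 needs at least 2 labeled exposures")
        t2 = stats.t.ppf(1 - (1 - ci2) / 2, df2)
        test2 = summed_sem * t2
        stage2 = abs(sum_dd) >= test2
        return pd.Series({
            "n_exposures": n_exp, "avg_sem": avg_sem, "test_value_1": test1,
            "n_significant_exposures": n_sig, "stage1_pass": stage1,
            "sum_dD": sum_dd, "summed_sem": summed_sem, "test_value_2": test2,
            "stage2_pass": stage2, "significant": bool(stage1 and stage2),
            "sign": int(np.sign(sum_dd)),
        })

    peptides = (merged.groupby(PEPTIDE_KEY, sort=False)
                .apply(per_peptide, include_groups=False).reset_index())
    for col in ("stage1_pass", "stage2_pass", "significant"):
        peptides[col] = peptides[col].astype(bool)
    exposures = merged.merge(peptides[PEPTIDE_KEY + ["test_value_1"]], on=PEPTIDE_KEY)
    exposures["exposure_significant"] = exposures["dD"].abs() >= exposures["test_value_1"]
    params = {"ci1": ci1, "ci2": ci2, "pooling": pooling,
              "df_stage2": df_stage2,
              "state_a": summary_a["state"].iloc[0] if len(summary_a) else None,
              "state_b": summary_b["state"].iloc[0] if len(summary_b) else None}
    return DifferentialResult(peptides, exposures, params, audit)


def residue_level_map(result: DifferentialResult | pd.DataFrame,
                      protein_length: int, aggregation: str = "mean",
                      value: str = "sum_dD",
                      exclude_prolines: bool = False) -> pd.DataFrame:
    """Project per-peptide differences onto residues.

    Each residue covered by at least one peptide receives the aggregate
    (mean, median, min or max) of the covering peptides' ``value`` column
    (default: summed ΔD over labeled exposures).  Each peptide's first
    residue is excluded (its amide loses label to fast back-exchange).
    Residues covered by no peptide are explicitly flagged ``covered=False``
    with NaN values — "no data" is never encoded as 0.

    Returns a DataFrame indexed by residue (1-based) with columns
    ``value, rel_value, n_peptides, frac_significant, covered``.
    """
    aggfun = {"mean": np.mean, "median": np.median,
              "min": np.min, "max": np.max}.get(aggregation)
    if aggfun is None:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    pep = result.peptides if isinstance(result, DifferentialResult) else result
    values: list[list] = [[] for _ in range(protein_length + 1)]
    rel_values: list[list] = [[] for _ in range(protein_length + 1)]
    sig: list[list] = [[] for _ in range(protein_length + 1)]
    for row in pep.itertuples(index=False):
        if row.end > protein_length:
            raise ValueError(f"peptide {row.start}-{row.end} exceeds protein length")
        v = getattr(row, value)
        mu = max(len(row.sequence) - row.sequence.upper().count("P") - 1, 0)
        rel = v / mu if mu > 0 else np.nan
        for r in range(row.start + 1, row.end + 1):
            if exclude_prolines and row.sequence[r - row.start - 1].upper() == "P":
                continue
            values[r].append(v)
            rel_values[r].append(rel)
            sig[r].append(bool(row.significant))
    records = []
    for r in range(1, protein_length + 1):
        if values[r]:
            records.append((r, aggfun(values[r]),
                            aggfun([x for x in rel_values[r] if not np.isnan(x)])
                            if any(not np.isnan(x) for x in rel_values[r]) else np.nan,
                            len(values[r]), float(np.mean(sig[r])), True))
        else:
            records.append((r, np.nan, np.nan, 0, np.nan, False))
    return (pd.DataFrame(records, columns=["residue", "value", "rel_value",
                                           "n_peptides", "frac_significant",
                                           "covered"])
            .set_index("residue"))


def coverage_metrics(peptides, protein_length: int):
    """Sequence coverage (%) and redundancy of a peptide map.

    ``peptides`` may be a :class:`~hdxconf.synthetic.PeptideMap`, a
    DataFrame with ``start``/``end`` columns, or an iterable of
    ``(start, end)``.  Coverage counts residues inside at least one
    peptide; redundancy is the mean number of covering peptides over the
    covered residues, and is NaN (undefined) for an empty map.
    """
    if hasattr(peptides, "intervals"):
        intervals = peptides.intervals
    elif isinstance(peptides, pd.DataFrame):
        intervals = list(zip(peptides["start"], peptides["end"]))
    else:
        intervals = [(s, e) for s, e, *_ in peptides]
    counts = np.zeros(protein_length + 1, dtype=int)
    for s, e in intervals:
        if not (1 <= s <= e <= protein_length):
            raise ValueError(f"peptide {s}-{e} outside protein of length {protein_length}")
        counts[s:e + 1] += 1
    covered = counts[1:] > 0
    coverage = 100.0 * covered.sum() / protein_length
    redundancy = float(counts[1:][covered].mean()) if covered.any() else float("nan")
    return coverage, redundancy
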