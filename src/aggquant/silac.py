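"""SILAC light/heavy quantification and significance calling.

Peptide-level light/heavy extracted-ion ratios against isotopically labeled
internal standards are rolled up to protein log2 ratios (median across
peptides and gel regions), differenced between transfection conditions,
recentered on the population means, and tested against a one-tailed 95%
rule: a difference is significant when it exceeds 1.64 times the sample
standard deviation of the recentered null-like population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("mock", "tdp43", "tdps6")
#: Difference columns: 43-Mock, S6-Mock, and S6-43 log2 ratio differences.
COMPARISONS = ("d43", "ds6", "ds6_43")
#: One-tailed 95% normal quantile used for the significance cutoffs.
Z_ONE_TAILED_95 = 1.64

GROUP_BOTH = "group1_both"
GROUP_S6 = "group2_s6"
GROUP_43 = "group3_43"
GROUP_LOST_IN_S6 = "group4_lost_in_s6"
UNCHANGED = "unchanged"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class QuantRecord:
    """Paired light/heavy intensities for one peptide in one mixture."""

    peptide: str
    condition: str
    replicate: int
    light_intensity: float
    heavy_intensity: float
    gel_region: str = ""


@dataclass
class RollupResult:
    log2_ratio: float
    dispersion: float
    n_peptides: int
    rejected: list[tuple[QuantRecord, str]] = field(default_factory=list)


def protein_log2_ratio(records: list[QuantRecord]) -> RollupResult:
    """Median peptide-level log2(light/heavy) for one protein/condition.

    Records with a nonpositive channel are rejected with a reason and do not
    contribute.  Dispersion is the sample SD across contributing records.
    """
    ratios: list[float] = []
    rejected: list[tuple[QuantRecord, str]] = []
    for r in records:
        if r.light_intensity <= 0:
            rejected.append((r, "nonpositive light intensity"))
        elif r.heavy_intensity <= 0:
            rejected.append((r, "nonpositive heavy intensity"))
        else:
            ratios.append(np.log2(r.light_intensity / r.heavy_intensity))
    if not ratios:
        raise ValueError("no quantifiable records (all channels missing or nonpositive)")
    arr = np.asarray(ratios)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return RollupResult(
        log2_ratio=float(np.median(arr)),
        dispersion=sd,
        n_peptides=arr.size,
        rejected=rejected,
    )


def recenter(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Subtract the population mean; returns (recentered, mean used)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("recentering requires at least 2 values")
    mean = float(np.mean(arr))
    return arr - mean, mean


def significance_cutoffs(
    recentered: dict[str, np.ndarray], z: float = Z_ONE_TAILED_95
) -> dict[str, float]:
    """Per-comparison cutoff = z x sample SD of the recentered differences."""
    cutoffs: dict[str, float] = {}
    for name, values in recentered.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 3:
            raise ValueError(f"cutoff for {name!r} requires >= 3 proteins")
        cutoffs[name] = z * float(np.std(arr, ddof=1))
    return cutoffs


def fold_change(log2_difference: float) -> float:
    """Linear fold change ``2**x``, presentation-rounded to the nearest
    integer when >= 2 (two decimals otherwise)."""
    fold = 2.0 ** float(log2_difference)
    return float(round(fold)) if fold >= 2 else round(fold, 2)


@dataclass(frozen=True)
class SignificanceCall:
    """Group label under the 1.64-SD rule, with the lost-in-S6 co-marking."""

    label: str
    direction: str | None
    lost_in_s6: bool
    not_evaluable: tuple[str, ...] = ()


def classify(
    d43: float | None,
    ds6: float | None,
    ds6_43: float | None,
    cutoffs: dict[str, float],
) -> SignificanceCall:
    """Classify one protein's recentered differences.

    Group 1: both mock-relative differences significant with the same sign.
    Group 2: only the S6-Mock difference significant.  Group 3: only the
    43-Mock difference.  Group 4 (lost in TDP-S6) is the signed one-tailed
    condition ``ds6_43 < -cutoff`` and attaches in addition to groups 1-3.
    Missing comparisons yield a partial call listing what was not evaluable.
    """
    missing = tuple(
        name
        for name, value in zip(COMPARISONS, (d43, ds6, ds6_43))
        if value is None
    )
    sig43 = d43 is not None and abs(d43) > cutoffs["d43"]
    sig_s6 = ds6 is not None and abs(ds6) > cutoffs["ds6"]
    lost = ds6_43 is not None and ds6_43 < -cutoffs["ds6_43"]

    if sig43 and sig_s6 and np.sign(d43) == np.sign(ds6):
        label = GROUP_BOTH
        direction = "up" if d43 > 0 else "down"
    elif sig_s6:
        label = GROUP_S6
        direction = "up" if ds6 > 0 else "down"
    elif sig43:
        label = GROUP_43
        direction = "up" if d43 > 0 else "down"
    elif lost:
        label = GROUP_LOST_IN_S6
        direction = "down"
    elif missing and not (sig43 or sig_s6 or lost):
        label = NOT_EVALUABLE
        direction = None
    else:
        label = UNCHANGED
        direction = None
    return SignificanceCall(
        label=label, direction=direction, lost_in_s6=lost, not_evaluable=missing
    )


@dataclass
class QuantSummary:
    """Population-level audit trail of a quantification run."""

    recentering_means: dict[str, float]
    cutoffs: dict[str, float]
    n_proteins: int
    n_complete: int
    n_rejected_records: int


def quantify_proteins(
    features: pd.DataFrame,
    exclude_modified: bool = True,
    z: float = Z_ONE_TAILED_95,
) -> tuple[pd.DataFrame, QuantSummary]:
    """Full protein-level quantification from a peptide feature table.

    ``features`` columns: peptide, protein_group, condition, replicate,
    gel_region, light_intensity, heavy_intensity, and optionally ``mods``
    (modified peptides are excluded from protein rollup when
    ``exclude_modified`` is set, so that modification stoichiometry can be
    normalized against the unmodified protein level).

    Per replicate, each protein/condition is rolled up to the median
    peptide log2(light/heavy); differences between conditions are formed
    within replicate and averaged across replicates.  Proteins quantified in
    all three conditions in both replicates form the population used for
    recentering and for the 1.64-SD cutoffs; the remainder keep partial
    calls.  Returns the protein table and a :class:`QuantSummary`.
    """
    df = features.copy()
    if exclude_modified and "mods" in df.columns:
        df = df[df["mods"].fillna("") == ""]
    ok = (df["light_intensity"] > 0) & (df["heavy_intensity"] > 0)
    n_rejected = int((~ok).sum())
    df = df[ok]
    df = df.assign(log2_ratio=np.log2(df["light_intensity"] / df["heavy_intensity"]))

    rollup = (
        df.groupby(["protein_group", "replicate", "condition"])["log2_ratio"]
        .median()
        .unstack("condition")
    )
    pep_counts = df.groupby(["protein_group", "condition"])["peptide"].nunique().unstack()

    diffs = pd.DataFrame(
        {
            "d43": rollup.get("tdp43") - rollup.get("mock"),
            "ds6": rollup.get("tdps6") - rollup.get("mock"),
            "ds6_43": rollup.get("tdps6") - rollup.get("tdp43"),
        }
    )
    per_protein = diffs.groupby(level="protein_group").mean()

    replicates = sorted(df["replicate"].unique())
    have_all = rollup[list(c for c in CONDITIONS if c in rollup.columns)].notna().all(axis=1)
    n_reps_complete = have_all.groupby(level="protein_group").sum()
    complete = (n_reps_complete >= len(replicates)) & (
        rollup.columns.size == len(CONDITIONS)
    )
    complete = complete.reindex(per_protein.index, fill_value=False)

    means: dict[str, float] = {}
    recentered_pop: dict[str, np.ndarray] = {}
    table = per_protein.copy()
    for comp in COMPARISONS:
        pop = per_protein.loc[complete, comp].dropna().to_numpy()
        recentered, mean = recenter(pop)
        means[comp] = mean
        recentered_pop[comp] = recentered
        table[comp] = per_protein[comp] - mean
        table[f"{comp}_raw"] = per_protein[comp]
    cutoffs = significance_cutoffs(recentered_pop, z=z)

    calls = [
        classify(
            None if pd.isna(row.d43) else row.d43,
            None if pd.isna(row.ds6) else row.ds6,
            None if pd.isna(row.ds6_43) else row.ds6_43,
            cutoffs,
        )
        for row in table.itertuples()
    ]
    table["group"] = [c.label for c in calls]
    table["direction"] = [c.direction or "" for c in calls]
    table["lost_in_s6"] = [c.lost_in_s6 for c in calls]
    table["complete"] = complete
    for cond in CONDITIONS:
        if cond in pep_counts.columns:
            table[f"n_peptides_{cond}"] = (
                pep_counts[cond].reindex(table.index).fillna(0).astype(int)
            )
    table = table.sort_index()

    summary = QuantSummary(
        recentering_means=means,
        cutoffs=cutoffs,
        n_proteins=len(table),
        n_complete=int(complete.sum()),
        n_rejected_records=n_rejected,
    )
    return table, summary


def triple_map(
    protein_table: pd.DataFrame, y_axis: str = "ds6_43"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Map coordinates for the triple-SILAC difference scatter.

    x is the recentered 43-Mock difference; y defaults to the recentered
    S6-43 difference (configurable to ``ds6``).  The axis assignment is
    returned as metadata alongside the coordinate table.
    """
    if y_axis not in ("ds6_43", "ds6"):
        raise ValueError(f"y_axis must be 'ds6_43' or 'ds6', got {y_axis!r}")
    coords = pd.DataFrame(
        {
            "x": protein_table["d43"],
            "y": protein_table[y_axis],
            "group": protein_table["group"],
            "lost_in_s6": protein_table["lost_in_s6"],
        }
    )
    meta = {"x": "d43 (recentered)", "y": f"{y_axis} (recentered)"}
    return coords, meta
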