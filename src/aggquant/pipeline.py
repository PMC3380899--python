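"""Pipeline orchestration, configuration, and report emission.

Runs the stages (PSM filtering -> SILAC quantification -> significance ->
modification stoichiometry -> targeted quantification) over the documented
TSV inputs, writes report tables, and can re-validate the shipped
reference tables cell by cell.
"""

from __future__ import annotations

import importlib.metadata
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chem, fdr, io, ptm, silac, targeted


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and all tunable parameters of one run."""

    outdir: str
    fasta: str | None = None
    features: str | None = None
    psm: str | None = None
    targeted_scans: str | None = None
    traces: str | None = None
    run_filter: bool = True
    run_quantify: bool = True
    run_ptm: bool = True
    run_targeted: bool = True
    target_fdr: float = 0.01
    ppm_limit: float = 15.0
    cutoff_z: float = silac.Z_ONE_TAILED_95
    ci_mode: str = "t"
    fragment_tolerance: float = 0.5
    experimental: str = "experimental"
    control: str = "control"
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """Paths of everything one pipeline run wrote."""

    tables: dict[str, str] = field(default_factory=dict)
    log: str = ""


def _version() -> str:
    try:
        return importlib.metadata.version("aggquant")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the toggled stages and emit the report bundle.

    Outputs (as toggled): accepted-PSM table + threshold report, the
    protein quantification table with significance groups, the triple-map
    coordinate table, the modification stoichiometry table, and the
    targeted summary, plus a run log echoing parameters, recentering means
    and cutoffs.  Identical config + inputs produce identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    log_lines = [
        f"aggquant {_version()}",
        f"seed: {config.seed}",
        f"parameters: target_fdr={config.target_fdr} ppm_limit={config.ppm_limit} "
        f"cutoff_z={config.cutoff_z} ci_mode={config.ci_mode}",
    ]

    accepted: list[fdr.PSM] = []
    if config.run_filter:
        if config.psm is None or not Path(config.psm).exists():
            raise FileNotFoundError(f"PSM table not found: {config.psm}")
        psms = io.read_psm_tsv(config.psm)
        result = fdr.dynamic_filter(
            psms, target_fdr=config.target_fdr, ppm_limit=config.ppm_limit
        )
        accepted = result.accepted
        path = out / "accepted_psms.tsv"
        io.write_psm_tsv(result.accepted, str(path))
        bundle.tables["accepted_psms"] = str(path)
        report = out / "filter_report.txt"
        with open(report, "w") as fh:
            fh.write(f"input PSMs\t{len(psms)}\n")
            fh.write(f"accepted\t{result.nt}\tdecoy\t{result.nd}\n")
            fh.write(f"psm_fdr\t{result.fdr_estimate:.6f}\n")
            fh.write(f"protein_fdr\t{result.protein_fdr:.6f}\n")
            fh.write(f"protein_groups\t{len(result.protein_groups)}\n")
            fh.write(
                f"single_peptide_groups\t{len(result.single_peptide_groups)}\n"
            )
            for key in sorted(result.thresholds):
                xc, dc = result.thresholds[key]
                fh.write(f"threshold\t{key[0]}\t{key[1]}+\txcorr>={xc:.2f}\tdcn>={dc:.2f}\n")
            for line in result.diagnostics:
                fh.write(f"note\t{line}\n")
        bundle.tables["filter_report"] = str(report)
        log_lines.append(
            f"filter: {result.nt} accepted, protein FDR {result.protein_fdr:.4f}"
        )

    protein_table = None
    if config.run_quantify:
        if config.features is None or not Path(config.features).exists():
            raise FileNotFoundError(f"feature table not found: {config.features}")
        features = io.read_feature_tsv(config.features)
        protein_table, summary = silac.quantify_proteins(features, z=config.cutoff_z)
        path = out / "protein_table.tsv"
        protein_table.round(6).to_csv(path, sep="\t")
        bundle.tables["protein_table"] = str(path)
        significant = protein_table[
            (protein_table["group"] != silac.UNCHANGED)
            & (protein_table["group"] != silac.NOT_EVALUABLE)
        ]
        sig_path = out / "significant_proteins.tsv"
        significant.round(6).to_csv(sig_path, sep="\t")
        bundle.tables["significant_proteins"] = str(sig_path)
        coords, meta = silac.triple_map(protein_table)
        map_path = out / "triple_map.tsv"
        coords.round(6).to_csv(map_path, sep="\t")
        bundle.tables["triple_map"] = str(map_path)
        log_lines.append(f"triple map axes: x={meta['x']} y={meta['y']}")
        log_lines.append(
            "recentering means: "
            + " ".join(f"{k}={v:.4f}" for k, v in summary.recentering_means.items())
        )
        log_lines.append(
            "cutoffs (z*SD): "
            + " ".join(f"{k}={v:.4f}" for k, v in summary.cutoffs.items())
        )
        log_lines.append(
            f"quantified {summary.n_proteins} proteins "
            f"({summary.n_complete} complete, "
            f"{summary.n_rejected_records} records rejected)"
        )

    if config.run_ptm:
        if protein_table is None:
            raise ValueError("PTM stage requires the quantify stage")
        features = io.read_feature_tsv(config.features)
        database = io.read_fasta(config.fasta) if config.fasta else None
        source = accepted if accepted else (
            io.read_psm_tsv(config.psm) if config.psm else []
        )
        candidates = ptm.detect_ptm_candidates(source, database=database)
        sites = _quantify_ptm_sites(candidates, features, protein_table)
        ptm_table = ptm.stoichiometry_table(sites)
        path = out / "ptm_table.tsv"
        ptm_table.to_csv(path, sep="\t", index=False)
        bundle.tables["ptm_table"] = str(path)
        log_lines.append(f"ptm: {len(ptm_table)} site rows")

    if config.run_targeted:
        scans = io.read_targeted_tsv(config.targeted_scans)
        traces = io.read_trace_tsv(config.traces)
        summary_df = _summarize_targeted(scans, traces, config)
        path = out / "targeted_summary.tsv"
        summary_df.round(6).to_csv(path, sep="\t", index=False)
        bundle.tables["targeted_summary"] = str(path)
        log_lines.append(f"targeted: {len(summary_df)} peptides summarized")

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    bundle.log = str(log_path)
    return bundle


def _quantify_ptm_sites(
    candidates: pd.DataFrame, features: pd.DataFrame, protein_table: pd.DataFrame
) -> list[ptm.PTMSiteQuant]:
    """Join detected sites with their modified-peptide features and the
    parent protein's unmodified percent-of-control."""
    sites: list[ptm.PTMSiteQuant] = []
    if candidates.empty:
        return sites
    features = features.copy()
    features["mods"] = features["mods"].fillna("")
    for (protein, site), grp in candidates.groupby(["protein", "site"]):
        peptide = grp["peptide"].iloc[0]
        bare = chem.parse_flanked(peptide).sequence
        rows = features[
            (features["protein_group"] == protein)
            & (features["peptide"] == bare)
            & (features["mods"] != "")
        ]
        if rows.empty:
            continue
        intensities: dict[str, tuple[float, float]] = {}
        for cond, sub in rows.groupby("condition"):
            intensities[cond] = (
                float(sub["light_intensity"].mean()),
                float(sub["heavy_intensity"].mean()),
            )
        if "mock" not in intensities:
            continue
        unmod = None
        if protein in protein_table.index:
            unmod = ptm.unmodified_percent_of_mock(
                protein_table.loc[protein, ["d43_raw", "ds6_raw"]].rename(
                    {"d43_raw": "d43", "ds6_raw": "ds6"}
                )
            )
        sites.append(
            ptm.quantify_site(protein, site, peptide, intensities, unmod)
        )
    return sites


def _summarize_targeted(
    scans: pd.DataFrame, traces: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Targeted summary: fragment-summed AGC-corrected targets normalized to
    trace-quantified (AGC-free) reference peptides.

    The required fragment list for each target is the three most intense
    fragments of its first control scan; peptides appearing in the trace
    table are the normalization references.
    """
    required: dict[str, list[float]] = {}
    for pid, grp in scans.groupby("peptide_id"):
        first = grp.sort_values(["sample", "replicate"]).iloc[0]
        peaks = [
            (float(p.split(":")[0]), float(p.split(":")[1]))
            for p in str(first["fragments"]).split(";")
            if p
        ]
        top = sorted(peaks, key=lambda p: -p[1])[:3]
        required[pid] = [mz for mz, _ in top]
    target_intensities = targeted.quantify_scan_table(
        scans, required, tolerance=config.fragment_tolerance
    )
    references = targeted.quantify_trace_table(traces)
    rows = []
    for pid in sorted(target_intensities):
        result = targeted.normalize_and_summarize(
            target_intensities[pid],
            references,
            experimental=config.experimental,
            control=config.control,
            peptide_id=pid,
            ci_mode=config.ci_mode,
        )
        rows.append(
            {
                "peptide_id": pid,
                "mean_log2": result.mean_log2,
                "ci95": result.ci95,
                "percent_change": result.percent_change,
                "n_values": result.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference-table fixtures and validation


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a shipped reference table (``significant_changers``,
    ``methylation_sites``, ``gg_reference_peptides``) as strings."""
    path = resources.files("aggquant").joinpath(f"tables/{name}.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def _ulp(printed: str) -> float:
    """One unit in the last printed digit of a decimal string."""
    printed = printed.strip()
    if "." in printed:
        return 10.0 ** -(len(printed) - printed.index(".") - 1)
    return 1.0


def validate_fixtures(
    gg_reference: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    changers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recompute every derivable reference-table cell; report per-cell pass/fail.

    Masses must agree within one unit in the fourth decimal place (the
    printed values are rounded or truncated from unrounded intermediates).
    Ratio and percent cells recomputed from the printed intensities must
    agree within max(one last-digit unit, 1%), since the printed
    intensities are themselves rounded to three significant figures.
    Log2-difference arithmetic must close within 0.015 (three 2-dp
    roundings).
    """
    t5 = gg_reference if gg_reference is not None else load_reference_table("gg_reference_peptides")
    t4 = methylation if methylation is not None else load_reference_table("methylation_sites")
    t1 = changers if changers is not None else load_reference_table("significant_changers")
    checks: list[dict] = []

    def add(table: str, row: str, cell: str, expected: str, computed: float, tol: float):
        exp = float(expected)
        checks.append(
            {
                "table": table,
                "row": row,
                "cell": cell,
                "expected": exp,
                "computed": computed,
                "tolerance": tol,
                "ok": abs(computed - exp) <= tol,
            }
        )

    for _, row in t5.iterrows():
        pep = chem.parse_flanked(row["peptide"])
        mh = chem.monoisotopic_mass(pep).mh
        add("gg_reference", row["site"], "mh", row["mh_printed"], round(mh, 4), 0.00011)

    for _, row in t4.iterrows():
        pep = chem.parse_flanked(row["peptide"])
        mh = chem.monoisotopic_mass(pep).mh
        add("methylation", row["sites"], "expected_mh", row["expected_mh"], round(mh, 4), 0.0002)
        ratio = {}
        for cond in ("wt", "s6", "mock"):
            light = float(row[f"light_{cond}"])
            heavy = float(row[f"heavy_{cond}"])
            ratio[cond] = ptm.modified_peptide_ratio(light, heavy)
            printed = row[f"ratio_{cond}"]
            add(
                "methylation",
                row["sites"],
                f"ratio_{cond}",
                printed,
                float(ptm.sig3(ratio[cond])),
                max(_ulp(printed), 0.01 * float(printed)),
            )
        for cond in ("wt", "s6"):
            unnorm = 100.0 * ratio[cond] / ratio["mock"]
            printed = row[f"unnorm_pct_{cond}"]
            add(
                "methylation",
                row["sites"],
                f"unnorm_pct_{cond}",
                printed,
                float(ptm.sig3(unnorm)),
                max(_ulp(printed), 0.01 * float(printed)),
            )
            norm = 100.0 * unnorm / float(row[f"unmod_pct_{cond}"])
            printed = row[f"norm_pct_{cond}"]
            add(
                "methylation",
                row["sites"],
                f"norm_pct_{cond}",
                printed,
                float(ptm.sig3(norm)),
                max(_ulp(printed), 0.01 * float(printed)),
            )

    for _, row in t1.iterrows():
        closed = float(row["ds6"]) - float(row["d43"])
        add("changers", row["gene"], "ds6_43", row["ds6_43"], round(closed, 4), 0.015)
    tardbp = t1[t1["gene"] == "TARDBP"].iloc[0]
    add("changers", "TARDBP", "fold_43", "11", silac.fold_change(float(tardbp["d43"])), 0.5)
    add("changers", "TARDBP", "fold_s6", "80", silac.fold_change(float(tardbp["ds6"])), 0.5)

    return pd.DataFrame(checks)
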