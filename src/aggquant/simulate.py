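"""Synthetic experiment generator with known ground truth.

Emulates the study design end to end: three transfection conditions (mock
and two overexpression models) measured against a SILAC heavy internal
standard in two replicates, a ~585-protein quantified population whose null
log2 ratio differences are Gaussian, a small spiked set of true changers,
decoy PSMs with configurable score distributions, condition-dependent
modification stoichiometry, and targeted scans obeying the AGC inject-time
law.  Every output is deterministic per seed and a ``truth.json`` manifest
records all ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, io

#: Approximate human proteome residue frequencies (normalized at use).
RESIDUE_FREQ = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "E": 7.1, "Q": 4.8,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.3, "W": 1.2, "Y": 2.7, "V": 6.0,
}


@dataclass
class PTMSiteSpec:
    """A simulated modification site with per-condition stoichiometry."""

    protein_index: int
    mod: str  # registry name, e.g. "GG" or "Me2"
    stoichiometry: dict[str, float]  # condition -> site occupancy in (0, 1]


@dataclass
class TargetedPeptideSpec:
    """A simulated targeted precursor with a true experimental/control effect."""

    peptide_id: str
    sequence: str
    true_log2: float  # log2(experimental/control)
    is_reference: bool = False
    abundance: float = 1e6


def default_ptm_sites() -> list[PTMSiteSpec]:
    return [
        # constitutive methylation: stoichiometry tracks protein level
        PTMSiteSpec(0, "Me2", {"mock": 0.20, "tdp43": 0.20, "tdps6": 0.20}),
        # induced methylation: doubled occupancy in both models
        PTMSiteSpec(1, "Me2", {"mock": 0.10, "tdp43": 0.20, "tdps6": 0.20}),
        # ubiquitin GG remnant induced in the aggregate-prone model only
        PTMSiteSpec(2, "GG", {"mock": 0.05, "tdp43": 0.05, "tdps6": 0.15}),
    ]


def default_targeted_peptides() -> list[TargetedPeptideSpec]:
    return [
        TargetedPeptideSpec("s6_junction", "FGVHLISNVYGR", 0.70),
        TargetedPeptideSpec("shared_rrm1", "FTEYETQVK", 2.30),
        TargetedPeptideSpec("eif4a1", "DQIYDIFQK", 1.20),
        TargetedPeptideSpec("tpi_ref1", "HVFGESDELIGQK", 0.0, is_reference=True),
        TargetedPeptideSpec("tpi_ref2", "VVLAYEPVWAIGTGK", 0.0, is_reference=True),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; the defaults reproduce the
    population structure of the study: 585 quantified proteins, 35 up / 6
    down spiked changers, null difference SDs 0.55/0.54/0.40 so the 1.64-SD
    cutoffs land near +/-0.9/0.9/0.65."""

    seed: int
    n_proteins: int = 585
    n_spiked_up: int = 35
    n_spiked_down: int = 6
    null_sd: tuple[float, float, float] = (0.55, 0.54, 0.40)
    spike_low: float = 1.2
    spike_high: float = 3.0
    peptides_per_protein_mean: float = 8.0
    intensity_noise_sd: float = 0.35  # log2 SD of peptide-level ratio noise
    missing_channel_rate: float = 0.01
    replicates: int = 2
    protein_length_low: int = 150
    protein_length_high: int = 700
    # PSM score model
    decoy_fraction: float = 0.30
    false_target_fraction: float = 0.01
    target_xcorr: tuple[float, float] = (3.2, 0.8)
    decoy_xcorr: tuple[float, float] = (1.4, 0.45)
    target_delta_cn: tuple[float, float] = (0.40, 0.12)
    decoy_delta_cn: tuple[float, float] = (0.08, 0.04)
    target_ppm_sd: float = 3.0
    decoy_ppm_range: float = 40.0
    # PTM and targeted layers
    ptm_sites: list[PTMSiteSpec] = field(default_factory=default_ptm_sites)
    targeted: list[TargetedPeptideSpec] = field(default_factory=default_targeted_peptides)
    agc_constant: float = 5e7  # inject_time = min(150, C / flux)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory; unseeded generation is not supported")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if any(s <= 0 for s in self.null_sd):
            raise ValueError("null_sd components must be positive")
        if self.n_spiked_up + self.n_spiked_down > self.n_proteins:
            raise ValueError("more spiked proteins than proteins")


def _protein_id(i: int) -> str:
    return f"PROT{i + 1:04d}"


def generate_proteome(config: SimulationConfig, fasta_path: str) -> dict[str, str]:
    """Random protein sequences with realistic residue frequencies.

    Each protein is resampled until it yields at least 3 fully tryptic
    peptides of length >= 6 (no missed cleavages), so every protein is
    quantifiable.  Deterministic per seed; returns {id: sequence} and
    writes a wrapped FASTA.
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(RESIDUE_FREQ))
    probs = np.array(list(RESIDUE_FREQ.values()))
    probs = probs / probs.sum()
    proteins: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(config.protein_length_low, config.protein_length_high))
        while True:
            seq = "".join(rng.choice(letters, size=length, p=probs))
            peps = _tryptic_peptides(seq)
            if len(peps) >= 3:
                break
        proteins[_protein_id(i)] = seq
    with open(fasta_path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid} synthetic\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j : j + 60] + "\n")
    return proteins


def _tryptic_peptides(seq: str, min_len: int = 6, max_len: int = 30) -> list[tuple[int, str]]:
    """Fully tryptic, zero-missed-cleavage peptides as (1-based start, seq)."""
    sites = chem.cleavage_sites(seq)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if min_len <= e - s <= max_len:
            out.append((s + 1, seq[s:e]))
    return out


def _spike_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """True per-protein log2 differences: correlated Gaussian null plus spikes."""
    sd43, sd_s6, sd_diff = config.null_sd
    cov = (sd43**2 + sd_s6**2 - sd_diff**2) / 2.0
    cov_matrix = np.array([[sd43**2, cov], [cov, sd_s6**2]])
    null = rng.multivariate_normal([0.0, 0.0], cov_matrix, size=config.n_proteins)
    d43, ds6 = null[:, 0].copy(), null[:, 1].copy()

    n_spiked = config.n_spiked_up + config.n_spiked_down
    spiked_idx = rng.choice(config.n_proteins, size=n_spiked, replace=False)
    up_idx = spiked_idx[: config.n_spiked_up]
    down_idx = spiked_idx[config.n_spiked_up :]
    pattern = np.empty(config.n_proteins, dtype=object)
    pattern[:] = ""
    # A spiked protein's true difference IS the spike effect (the null draw
    # is replaced in the affected comparison), so ground-truth recovery and
    # detection power are well defined.
    for idx in up_idx:
        effect = rng.uniform(config.spike_low, config.spike_high)
        mode = rng.choice(["both", "s6", "43"], p=[0.4, 0.3, 0.3])
        if mode in ("both", "43"):
            d43[idx] = effect
        if mode in ("both", "s6"):
            ds6[idx] = effect
        pattern[idx] = f"up_{mode}"
    for idx in down_idx:
        effect = rng.uniform(config.spike_low, config.spike_high)
        d43[idx] = -effect
        ds6[idx] = -effect
        pattern[idx] = "down_both"
    return pd.DataFrame(
        {
            "protein": [_protein_id(i) for i in range(config.n_proteins)],
            "d43": d43,
            "ds6": ds6,
            "spike": pattern,
        }
    ).set_index("protein")


def simulate_experiment(
    config: SimulationConfig, proteins: dict[str, str], outdir: str
) -> dict[str, str]:
    """Generate all pipeline inputs plus a ground-truth manifest.

    Writes ``features.tsv``, ``psm.tsv``, ``targeted.tsv``, ``traces.tsv``
    and ``truth.json`` under ``outdir`` and returns their paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    ids = list(proteins)
    if len(ids) != config.n_proteins:
        raise ValueError(
            f"config expects {config.n_proteins} proteins, FASTA has {len(ids)}"
        )
    for spec in config.ptm_sites:
        if spec.protein_index >= len(ids):
            raise ValueError(f"ptm site references absent protein {spec.protein_index}")

    truth_diffs = _spike_table(config, rng)
    mock_base = rng.normal(0.0, 0.30, size=config.n_proteins)
    ratio_by_cond = {
        "mock": mock_base,
        "tdp43": mock_base + truth_diffs["d43"].to_numpy(),
        "tdps6": mock_base + truth_diffs["ds6"].to_numpy(),
    }

    feature_rows: list[dict] = []
    peptide_catalog: list[tuple[str, int, str]] = []  # (protein, start, seq)
    for i, pid in enumerate(ids):
        seq = proteins[pid]
        peps = _tryptic_peptides(seq)
        n_pep = min(len(peps), max(3, int(rng.poisson(config.peptides_per_protein_mean))))
        chosen = [peps[j] for j in rng.choice(len(peps), size=n_pep, replace=False)]
        region = "low" if len(seq) < 330 else ("mid" if len(seq) < 520 else "high")
        for start, pep_seq in chosen:
            peptide_catalog.append((pid, start, pep_seq))
            base = float(rng.lognormal(mean=4.0, sigma=1.0))
            for cond in ("mock", "tdp43", "tdps6"):
                for rep in range(1, config.replicates + 1):
                    heavy = base * float(rng.lognormal(0.0, 0.15))
                    noise = rng.normal(0.0, config.intensity_noise_sd)
                    light = heavy * 2.0 ** (ratio_by_cond[cond][i] + noise)
                    if rng.random() < config.missing_channel_rate:
                        light = 0.0
                    feature_rows.append(
                        {
                            "peptide": pep_seq,
                            "mods": "",
                            "protein_group": pid,
                            "condition": cond,
                            "replicate": rep,
                            "gel_region": region,
                            "light_intensity": round(light, 3),
                            "heavy_intensity": round(heavy, 3),
                        }
                    )

    ptm_truth = _simulate_ptm_features(config, proteins, ids, ratio_by_cond, feature_rows, rng)

    features = pd.DataFrame(feature_rows, columns=io.FEATURE_COLUMNS)
    features_path = out / "features.tsv"
    features.to_csv(features_path, sep="\t", index=False)

    psm_path = out / "psm.tsv"
    false_ids = _simulate_psms(config, proteins, peptide_catalog, ptm_truth, rng, psm_path)

    targeted_path = out / "targeted.tsv"
    traces_path = out / "traces.tsv"
    targeted_truth = _simulate_targeted(config, rng, targeted_path, traces_path)

    truth = {
        "seed": config.seed,
        "null_sd": list(config.null_sd),
        "spiked": {
            pid: {
                "d43": float(truth_diffs.loc[pid, "d43"]),
                "ds6": float(truth_diffs.loc[pid, "ds6"]),
                "pattern": truth_diffs.loc[pid, "spike"],
            }
            for pid in truth_diffs.index[truth_diffs["spike"] != ""]
        },
        "true_differences": {
            pid: {
                "d43": float(truth_diffs.loc[pid, "d43"]),
                "ds6": float(truth_diffs.loc[pid, "ds6"]),
            }
            for pid in truth_diffs.index
        },
        "false_psm_ids": sorted(false_ids),
        "ptm_sites": ptm_truth,
        "targeted": targeted_truth,
        "config": _config_dict(config),
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {
        "features": str(features_path),
        "psm": str(psm_path),
        "targeted": str(targeted_path),
        "traces": str(traces_path),
        "truth": str(truth_path),
    }


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))


def _simulate_ptm_features(
    config: SimulationConfig,
    proteins: dict[str, str],
    ids: list[str],
    ratio_by_cond: dict[str, np.ndarray],
    feature_rows: list[dict],
    rng: np.random.Generator,
) -> list[dict]:
    """Append modified-peptide features whose light/heavy ratio reflects the
    configured site stoichiometry on top of the protein-level change.  The
    heavy internal standard carries the mock stoichiometry."""
    truth = []
    for spec in config.ptm_sites:
        pid = ids[spec.protein_index]
        seq = proteins[pid]
        mod_spec = chem.MODIFICATIONS[spec.mod]
        # A cleavage-blocking modification creates a peptide spanning the
        # modified K/R, so digest with the modification applied and keep the
        # peptide that contains the site.
        placed = None
        for pos in range(2, len(seq)):
            if seq[pos - 1] not in mod_spec.targets:
                continue
            rules = chem.DigestRules(max_missed_cleavages=0, min_length=6)
            try:
                peptides = chem.digest(seq, rules, mods=[(pos, mod_spec)], protein_id=pid)
            except chem.ChemistryError:
                continue
            covering = [
                p
                for p in peptides
                if p.start <= pos <= p.end and len(p.sequence) <= 30 and p.mods
            ]
            if covering:
                pep = covering[0]
                placed = (pep.start, pep.sequence, pos - pep.start + 1)
                break
        if placed is None:
            raise ValueError(f"no {spec.mod} site available in {pid}")
        start, pep_seq, pep_pos = placed
        site_label = f"{pep_seq[pep_pos - 1]}{start + pep_pos - 1}-{spec.mod}"
        base = float(rng.lognormal(mean=4.5, sigma=0.5))
        stoich_heavy = spec.stoichiometry["mock"]
        for cond in ("mock", "tdp43", "tdps6"):
            idx = spec.protein_index
            for rep in range(1, config.replicates + 1):
                heavy = base * stoich_heavy * float(rng.lognormal(0.0, 0.1))
                noise = rng.normal(0.0, config.intensity_noise_sd / 2)
                light = (
                    base
                    * spec.stoichiometry[cond]
                    * 2.0 ** (ratio_by_cond[cond][idx] + noise)
                )
                feature_rows.append(
                    {
                        "peptide": pep_seq,
                        "mods": f"{pep_pos}:{spec.mod}",
                        "protein_group": pid,
                        "condition": cond,
                        "replicate": rep,
                        "gel_region": "low",
                        "light_intensity": round(light, 3),
                        "heavy_intensity": round(heavy, 3),
                    }
                )
        truth.append(
            {
                "protein": pid,
                "site": site_label,
                "mod": spec.mod,
                "peptide": pep_seq,
                "peptide_position": pep_pos,
                "protein_start": start,
                "stoichiometry": dict(spec.stoichiometry),
                "expected_norm_pct": {
                    cond: 100.0 * spec.stoichiometry[cond] / spec.stoichiometry["mock"]
                    for cond in ("tdp43", "tdps6")
                },
            }
        )
    return truth


def _simulate_psms(
    config: SimulationConfig,
    proteins: dict[str, str],
    peptide_catalog: list[tuple[str, int, str]],
    ptm_truth: list[dict],
    rng: np.random.Generator,
    psm_path: Path,
) -> list[str]:
    """Write the PSM table; returns spectrum ids of false target matches."""
    from . import fdr as _fdr

    psms: list[_fdr.PSM] = []
    false_ids: list[str] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:06d}"

    def draw_scores(is_target_like: bool) -> tuple[float, float, float]:
        if is_target_like:
            xc = max(0.0, rng.normal(*config.target_xcorr))
            dc = float(np.clip(rng.normal(*config.target_delta_cn), 0.0, 1.0))
            ppm = rng.normal(0.0, config.target_ppm_sd)
        else:
            xc = max(0.0, rng.normal(*config.decoy_xcorr))
            dc = float(np.clip(rng.normal(*config.decoy_delta_cn), 0.0, 1.0))
            ppm = rng.uniform(-config.decoy_ppm_range, config.decoy_ppm_range)
        return xc, dc, ppm

    def make_psm(
        pep: chem.Peptide, protein_ids: tuple[str, ...], is_decoy: bool, target_like: bool
    ) -> _fdr.PSM:
        xc, dc, ppm = draw_scores(target_like)
        theo = chem.monoisotopic_mass(pep).mh
        return _fdr.PSM(
            spectrum_id=next_id(),
            peptide=pep,
            charge=int(rng.choice([2, 3, 4], p=[0.6, 0.3, 0.1])),
            xcorr=round(xc, 4),
            delta_cn=round(dc, 4),
            observed_mh=round(theo * (1.0 + ppm * 1e-6), 6),
            trypticity=str(rng.choice(["full", "partial"], p=[0.8, 0.2])),
            is_decoy=is_decoy,
            protein_ids=protein_ids,
        )

    for pid, start, pep_seq in peptide_catalog:
        pep = chem.Peptide(sequence=pep_seq, protein_id=pid, start=start)
        is_false = rng.random() < config.false_target_fraction
        psm = make_psm(pep, (pid,), is_decoy=False, target_like=not is_false)
        if is_false:
            false_ids.append(psm.spectrum_id)
        psms.append(psm)

    for entry in ptm_truth:
        pep = chem.Peptide(
            sequence=entry["peptide"],
            mods=[(entry["peptide_position"], chem.MODIFICATIONS[entry["mod"]])],
            protein_id=entry["protein"],
            start=entry["protein_start"],
        )
        psms.append(make_psm(pep, (entry["protein"],), is_decoy=False, target_like=True))

    n_decoys = int(config.decoy_fraction * len(peptide_catalog))
    picks = rng.choice(len(peptide_catalog), size=n_decoys, replace=True)
    for j in picks:
        pid, _start, pep_seq = peptide_catalog[int(j)]
        decoy_seq = pep_seq[::-1]
        pep = chem.Peptide(sequence=decoy_seq, protein_id=f"REV_{pid}")
        psms.append(make_psm(pep, (f"REV_{pid}",), is_decoy=True, target_like=False))

    io.write_psm_tsv(psms, str(psm_path))
    return false_ids


def _simulate_targeted(
    config: SimulationConfig,
    rng: np.random.Generator,
    targeted_path: Path,
    traces_path: Path,
) -> dict:
    """Targeted scans under the AGC law and reference XIC traces.

    Non-reference peptides are quantified from MS/MS fragments whose summed
    intensity scales with ion flux times the trap fill fraction; references
    are quantified from (AGC-free) precursor traces.  A per-sample loading
    factor multiplies every intensity and must cancel after reference
    normalization.
    """
    samples = ["control", "experimental"]
    loading = {
        (s, rep): float(rng.lognormal(0.0, 0.10))
        for s in samples
        for rep in range(1, config.replicates + 1)
    }
    scan_rows = []
    trace_rows = []
    truth: dict[str, dict] = {}
    for spec in config.targeted:
        pep = chem.Peptide(sequence=spec.sequence)
        ladder = chem.fragment_ladder(pep, ion_types=("y",))
        top = sorted(ladder, key=lambda kv: -kv[1])[:3]
        frag_mzs = [mz for _lab, mz in top]
        frag_weights = rng.dirichlet(np.ones(len(frag_mzs)) * 5.0)
        truth[spec.peptide_id] = {
            "true_log2": spec.true_log2,
            "is_reference": spec.is_reference,
            "fragments": [round(m, 4) for m in frag_mzs],
        }
        for sample in samples:
            effect = 2.0**spec.true_log2 if sample == "experimental" else 1.0
            for rep in range(1, config.replicates + 1):
                flux = (
                    spec.abundance
                    * effect
                    * loading[(sample, rep)]
                    * float(rng.lognormal(0.0, 0.05))
                )
                if spec.is_reference:
                    # triangular elution peak, apex proportional to flux
                    apex_t = 30.0 + float(rng.normal(0.0, 1.0))
                    for dt in np.linspace(-5, 5, 21):
                        inten = max(0.0, flux * (1.0 - abs(dt) / 5.0))
                        trace_rows.append(
                            {
                                "peptide_id": spec.peptide_id,
                                "sample": sample,
                                "replicate": rep,
                                "time": round(apex_t + dt, 3),
                                "intensity": round(inten, 3),
                            }
                        )
                else:
                    inject = min(150.0, config.agc_constant / flux)
                    total = flux * inject / 150.0
                    peaks = [
                        (round(mz, 4), round(total * w, 3))
                        for mz, w in zip(frag_mzs, frag_weights)
                    ]
                    peaks.append((round(rng.uniform(200, 300), 4), round(total * 0.05, 3)))
                    scan_rows.append(
                        {
                            "peptide_id": spec.peptide_id,
                            "sample": sample,
                            "replicate": rep,
                            "inject_time_ms": round(inject, 4),
                            "fragments": ";".join(f"{m}:{i}" for m, i in peaks),
                        }
                    )
    pd.DataFrame(scan_rows).to_csv(targeted_path, sep="\t", index=False)
    pd.DataFrame(trace_rows).to_csv(traces_path, sep="\t", index=False)
    return truth
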