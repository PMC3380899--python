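"""Plain-TSV readers/writers for the pipeline's table dialects.

Modifications are serialized as ``pos:name`` pairs joined by semicolons
(positions are 1-based within the peptide), protein lists as
semicolon-joined identifiers.
"""

from __future__ import annotations

import pandas as pd

from . import chem, fdr


def format_mods(mods: list[tuple[int, chem.ModificationSpec]]) -> str:
    return ";".join(f"{pos}:{spec.name}" for pos, spec in mods)


def parse_mods(text: str | float | None) -> list[tuple[int, chem.ModificationSpec]]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return []
    out = []
    for item in str(text).split(";"):
        pos, name = item.split(":")
        if name not in chem.MODIFICATIONS:
            raise chem.ChemistryError(f"unregistered modification {name!r}")
        out.append((int(pos), chem.MODIFICATIONS[name]))
    return out


PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "mods",
    "charge",
    "xcorr",
    "delta_cn",
    "observed_mh",
    "trypticity",
    "is_decoy",
    "protein_ids",
]


def write_psm_tsv(psms: list[fdr.PSM], path: str) -> None:
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide.sequence,
            "mods": format_mods(p.peptide.mods),
            "charge": p.charge,
            "xcorr": p.xcorr,
            "delta_cn": p.delta_cn,
            "observed_mh": p.observed_mh,
            "trypticity": p.trypticity,
            "is_decoy": p.is_decoy,
            "protein_ids": ";".join(p.protein_ids),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_tsv(path: str) -> list[fdr.PSM]:
    df = pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False)
    psms = []
    for row in df.itertuples():
        peptide = chem.Peptide(sequence=row.peptide, mods=parse_mods(row.mods))
        psms.append(
            fdr.PSM(
                spectrum_id=str(row.spectrum_id),
                peptide=peptide,
                charge=int(row.charge),
                xcorr=float(row.xcorr),
                delta_cn=float(row.delta_cn),
                observed_mh=float(row.observed_mh),
                trypticity=str(row.trypticity),
                is_decoy=str(row.is_decoy) in ("True", "true", "1"),
                protein_ids=tuple(str(row.protein_ids).split(";")),
            )
        )
    return psms


FEATURE_COLUMNS = [
    "peptide",
    "mods",
    "protein_group",
    "condition",
    "replicate",
    "gel_region",
    "light_intensity",
    "heavy_intensity",
]


def read_feature_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False).astype(
        {"replicate": int, "light_intensity": float, "heavy_intensity": float}
    )


def read_targeted_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").astype(
        {"replicate": int, "inject_time_ms": float}
    )


def read_trace_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").astype(
        {"replicate": int, "time": float, "intensity": float}
    )


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
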