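"""Modification-site quantification and stoichiometry normalization.

A modified peptide's light/heavy ratio in each condition is expressed as a
percent of the mock (control) ratio and then normalized to the parent
protein's unmodified-peptide percent of control, separating a change in
modification stoichiometry from a change in protein level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import chem, fdr

#: Modifications that define a PTM site (SILAC labels and Met oxidation are
#: bookkeeping, not sites).
SITE_MODS = ("GG", "Me1", "Me2")

#: Condition keys for the two overexpression models, relative to mock.
NON_MOCK = ("tdp43", "tdps6")


def sig3(x: float | None) -> float | None:
    """Round to 3 significant figures for reporting (full precision is kept
    internally)."""
    if x is None or x == 0:
        return x
    digits = 2 - int(math.floor(math.log10(abs(x))))
    return round(x, digits)


def modified_peptide_ratio(light: float, heavy: float) -> float | None:
    """Light/heavy ratio; ``None`` marks a not-quantifiable pair."""
    if light <= 0 or heavy <= 0:
        return None
    return light / heavy


@dataclass
class PTMSiteQuant:
    """One modification site's per-condition quantification (one table row)."""

    protein: str
    site: str
    peptide: str
    intensities: dict[str, tuple[float, float]]
    ratio: dict[str, float | None] = field(default_factory=dict)
    unnorm_percent: dict[str, float | None] = field(default_factory=dict)
    unmodified_percent: dict[str, float | None] = field(default_factory=dict)
    norm_percent: dict[str, float | None] = field(default_factory=dict)


def quantify_site(
    protein: str,
    site: str,
    peptide: str,
    intensities: dict[str, tuple[float, float]],
    unmodified_percent: dict[str, float] | None = None,
) -> PTMSiteQuant:
    """Fill all derived columns for one site.

    ``intensities`` maps condition -> (light, heavy).  The mock ratio must
    be quantifiable.  ``unmodified_percent`` maps non-mock condition -> the
    parent protein's unmodified-peptide percent of control; when missing,
    normalized values are marked unavailable.
    """
    q = PTMSiteQuant(protein=protein, site=site, peptide=peptide, intensities=intensities)
    for cond, (light, heavy) in intensities.items():
        q.ratio[cond] = modified_peptide_ratio(light, heavy)
    mock = q.ratio.get("mock")
    if mock is None:
        raise ValueError(f"site {site}: mock ratio is not quantifiable")
    for cond in NON_MOCK:
        r = q.ratio.get(cond)
        q.unnorm_percent[cond] = None if r is None else 100.0 * r / mock
        u = None if unmodified_percent is None else unmodified_percent.get(cond)
        q.unmodified_percent[cond] = u
        if q.unnorm_percent[cond] is None or u is None:
            q.norm_percent[cond] = None
        else:
            q.norm_percent[cond] = 100.0 * q.unnorm_percent[cond] / u
    return q


def stoichiometry_table(sites: list[PTMSiteQuant]) -> pd.DataFrame:
    """Report table mirroring the methylation/ubiquitination site layout:
    per-condition ratios, unnormalized percent of control, the protein's
    unmodified-peptide percent of control, and the normalized percent.
    Percentages and ratios are presented at 3 significant figures."""
    rows = []
    for q in sites:
        row: dict[str, object] = {
            "protein": q.protein,
            "site": q.site,
            "peptide": q.peptide,
        }
        for cond in ("tdp43", "tdps6", "mock"):
            if cond in q.intensities:
                row[f"light_{cond}"], row[f"heavy_{cond}"] = q.intensities[cond]
            row[f"ratio_{cond}"] = sig3(q.ratio.get(cond))
        for cond in NON_MOCK:
            row[f"unnorm_pct_{cond}"] = sig3(q.unnorm_percent.get(cond))
            row[f"unmodified_pct_{cond}"] = sig3(q.unmodified_percent.get(cond))
            row[f"norm_pct_{cond}"] = sig3(q.norm_percent.get(cond))
        rows.append(row)
    return pd.DataFrame(rows)


def detect_ptm_candidates(
    accepted: list["fdr.PSM"],
    database: dict[str, str] | None = None,
    site_mods: tuple[str, ...] = SITE_MODS,
) -> pd.DataFrame:
    """Site-annotated peptide list from accepted PSMs.

    Sites are numbered 1-based on the protein sequence (e.g. ``K145-GG``,
    ``R291-Me2``); a peptide with two modified residues yields two site
    records sharing the PSM.  The peptide's protein start position is taken
    from the peptide when present, otherwise located in ``database``.
    A residue mismatch between peptide and protein is an error.
    """
    rows = []
    for psm in accepted:
        pep = psm.peptide
        site_list = [(pos, spec) for pos, spec in pep.mods if spec.name in site_mods]
        if not site_list:
            continue
        protein_id = pep.protein_id or (psm.protein_ids[0] if psm.protein_ids else None)
        if protein_id is None:
            raise ValueError(f"PSM {psm.spectrum_id}: no protein for site numbering")
        start = pep.start
        if start is None:
            if database is None or protein_id not in database:
                raise ValueError(
                    f"PSM {psm.spectrum_id}: protein {protein_id} not in database"
                )
            idx = database[protein_id].find(pep.sequence)
            if idx < 0:
                raise ValueError(
                    f"PSM {psm.spectrum_id}: peptide {pep.sequence} not found in "
                    f"{protein_id}"
                )
            start = idx + 1
        if database is not None and protein_id in database:
            seq = database[protein_id]
            segment = seq[start - 1 : start - 1 + len(pep.sequence)]
            if segment != pep.sequence:
                raise ValueError(
                    f"PSM {psm.spectrum_id}: peptide does not match {protein_id} at "
                    f"position {start}"
                )
        for pos, spec in site_list:
            residue = pep.sequence[pos - 1]
            rows.append(
                {
                    "protein": protein_id,
                    "site": f"{residue}{start + pos - 1}-{spec.name}",
                    "mod": spec.name,
                    "peptide": chem.format_flanked(pep),
                    "spectrum_id": psm.spectrum_id,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["protein", "site", "mod", "peptide", "spectrum_id"])
    df = pd.DataFrame(rows)
    return df.sort_values(["protein", "site", "spectrum_id"]).reset_index(drop=True)


def unmodified_percent_of_mock(protein_diffs: pd.Series) -> dict[str, float]:
    """Convert a protein's raw (un-recentered) log2 differences vs mock into
    the unmodified-peptide percent-of-control values used for normalization:
    ``100 * 2**d`` for each non-mock condition (``d43`` -> tdp43, ``ds6`` ->
    tdps6)."""
    out: dict[str, float] = {}
    if "d43" in protein_diffs and pd.notna(protein_diffs["d43"]):
        out["tdp43"] = 100.0 * 2.0 ** float(protein_diffs["d43"])
    if "ds6" in protein_diffs and pd.notna(protein_diffs["ds6"]):
        out["tdps6"] = 100.0 * 2.0 ** float(protein_diffs["ds6"])
    return out
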