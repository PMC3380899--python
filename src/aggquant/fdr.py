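"""Grouped target-decoy filtering of peptide-spectrum matches.

PSMs are grouped by trypticity (full/partial) and precursor charge (2+, 3+,
4+), gated by precursor mass accuracy, and then filtered by per-group
(Xcorr, deltaCn) thresholds found on a grid ascending from fixed floors.
The false discovery rate is estimated from decoy matches as
``FDR = 2 * nd / nt`` and the binding constraint is the protein-level FDR
after protein-family grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from . import chem

XCORR_FLOOR = 1.0
DELTA_CN_FLOOR = 0.05
PPM_LIMIT = 15.0
XCORR_STEP = 0.1
DELTA_CN_STEP = 0.01
VALID_CHARGES = (2, 3, 4)


@dataclass
class PSM:
    """One spectrum-to-peptide match with search scores and a decoy flag."""

    spectrum_id: str
    peptide: chem.Peptide
    charge: int
    xcorr: float
    delta_cn: float
    observed_mh: float
    trypticity: str  # "full" | "partial"
    is_decoy: bool
    protein_ids: tuple[str, ...]

    @cached_property
    def theoretical_mh(self) -> float:
        return chem.monoisotopic_mass(self.peptide).mh

    @property
    def ppm_error(self) -> float:
        return (self.observed_mh - self.theoretical_mh) / self.theoretical_mh * 1e6


def estimate_fdr(accepted: list[PSM]) -> float:
    """``2 * nd / nt`` over the accepted set; 0 for empty input."""
    nt = len(accepted)
    if nt == 0:
        return 0.0
    nd = sum(1 for p in accepted if p.is_decoy)
    return 2.0 * nd / nt


def group_psms(
    psms: list[PSM],
) -> tuple[dict[tuple[str, int], list[PSM]], list[PSM]]:
    """Partition PSMs by (trypticity, charge); out-of-range charges are rejected.

    Returns ``(groups, rejected)``; the six possible groups are the product
    of {full, partial} and {2, 3, 4}.
    """
    groups: dict[tuple[str, int], list[PSM]] = {}
    rejected: list[PSM] = []
    for p in psms:
        if p.charge not in VALID_CHARGES or p.trypticity not in ("full", "partial"):
            rejected.append(p)
            continue
        groups.setdefault((p.trypticity, p.charge), []).append(p)
    return groups, rejected


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller identifier wins as root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def group_protein_families(
    accepted: list[PSM], decoy_prefix: str = "REV_"
) -> list[frozenset[str]]:
    """Merge proteins sharing any accepted peptide into families.

    Sharing is transitive: all proteins matched by one peptide are merged,
    and chains of shared peptides collapse into a single group.  Groups are
    returned sorted by their smallest member for determinism.
    """
    uf = _UnionFind()
    peptide_owners: dict[str, set[str]] = {}
    for p in accepted:
        key = chem.format_flanked(p.peptide)
        peptide_owners.setdefault(key, set()).update(p.protein_ids)
    for owners in peptide_owners.values():
        owners = sorted(owners)
        for a in owners:
            uf.union(owners[0], a)
    members: dict[str, set[str]] = {}
    for protein in uf.parent:
        members.setdefault(uf.find(protein), set()).add(protein)
    return sorted((frozenset(v) for v in members.values()), key=lambda g: min(g))


def group_is_decoy(group: frozenset[str], decoy_prefix: str = "REV_") -> bool:
    """A protein family is decoy only if every member is a decoy."""
    return all(chem.is_decoy_id(m, decoy_prefix) for m in group)


def protein_level_fdr(
    accepted: list[PSM], decoy_prefix: str = "REV_"
) -> tuple[float, list[frozenset[str]]]:
    groups = group_protein_families(accepted, decoy_prefix)
    if not groups:
        return 0.0, groups
    nd = sum(1 for g in groups if group_is_decoy(g, decoy_prefix))
    return 2.0 * nd / len(groups), groups


@dataclass
class FilterResult:
    """Outcome of dynamic threshold filtering."""

    thresholds: dict[tuple[str, int], tuple[float, float]]
    accepted: list[PSM]
    nd: int
    nt: int
    fdr_estimate: float  # PSM-level 2*nd/nt over the accepted set
    protein_fdr: float
    protein_groups: list[frozenset[str]]
    ppm_limit: float
    single_peptide_groups: list[frozenset[str]] = field(default_factory=list)
    rejected_charge: list[PSM] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)


def _best_pair(
    group: list[PSM], working_fdr: float
) -> tuple[tuple[float, float], list[PSM]]:
    """Grid search for the (xcorr, deltaCn) threshold pair that maximizes
    accepted target PSMs subject to group FDR <= ``working_fdr``.

    Ties break toward the lower xcorr threshold, then the lower deltaCn
    threshold.  Returns the empty acceptance when no pair is feasible.
    """
    xs = np.array([p.xcorr for p in group])
    ds = np.array([p.delta_cn for p in group])
    decoy = np.array([p.is_decoy for p in group])

    x_grid = np.arange(XCORR_FLOOR, max(xs.max(), XCORR_FLOOR) + XCORR_STEP, XCORR_STEP)
    d_grid = np.arange(
        DELTA_CN_FLOOR, max(ds.max(), DELTA_CN_FLOOR) + DELTA_CN_STEP, DELTA_CN_STEP
    )
    # Histogram counts per grid cell, then suffix sums give, for every
    # threshold pair, the number of PSMs with xcorr >= x and delta_cn >= d.
    x_bins = np.append(x_grid, np.inf)
    d_bins = np.append(d_grid, np.inf)
    h_all, _, _ = np.histogram2d(xs, ds, bins=[x_bins, d_bins])
    h_dec, _, _ = np.histogram2d(xs[decoy], ds[decoy], bins=[x_bins, d_bins])
    nt = np.flip(np.flip(h_all, 0).cumsum(0), 0)
    nt = np.flip(np.flip(nt, 1).cumsum(1), 1)
    nd = np.flip(np.flip(h_dec, 0).cumsum(0), 0)
    nd = np.flip(np.flip(nd, 1).cumsum(1), 1)

    feasible = (nt > 0) & (2.0 * nd <= working_fdr * nt)
    if not feasible.any():
        return (float(x_grid[-1]), float(d_grid[-1])), []
    targets = nt - nd
    best = np.where(feasible, targets, -1)
    flat = np.argmax(best)  # first occurrence = lowest xcorr, then lowest dcn
    i, j = np.unravel_index(flat, best.shape)
    thr_x, thr_d = float(x_grid[i]), float(d_grid[j])
    accepted = [p for p in group if p.xcorr >= thr_x and p.delta_cn >= thr_d]
    return (thr_x, thr_d), accepted


def dynamic_filter(
    psms: list[PSM],
    target_fdr: float = 0.01,
    ppm_limit: float = PPM_LIMIT,
    decoy_prefix: str = "REV_",
    max_rounds: int = 20,
) -> FilterResult:
    """Grouped dynamic threshold filtering to a protein-level FDR target.

    Each (trypticity, charge) group is gated at ``|ppm| <= ppm_limit`` and
    then filtered at the threshold pair maximizing accepted targets under a
    working PSM-level FDR; if the resulting global protein-level FDR (after
    family grouping) exceeds ``target_fdr``, the working rate is halved and
    the search repeats.  Infeasible inputs yield an empty acceptance with a
    diagnostic rather than an exception.
    """
    diagnostics: list[str] = []
    in_window = [p for p in psms if abs(p.ppm_error) <= ppm_limit]
    n_out = len(psms) - len(in_window)
    if n_out:
        diagnostics.append(f"{n_out} PSMs outside +/-{ppm_limit} ppm window")
    groups, rejected = group_psms(in_window)
    if rejected:
        diagnostics.append(f"{len(rejected)} PSMs with charge outside {VALID_CHARGES}")

    thresholds: dict[tuple[str, int], tuple[float, float]] = {}
    accepted: list[PSM] = []
    working = target_fdr
    for _ in range(max_rounds):
        thresholds = {}
        accepted = []
        for key in sorted(groups):
            thr, acc = _best_pair(groups[key], working)
            thresholds[key] = thr
            accepted.extend(acc)
        if not accepted:
            diagnostics.append(
                "no thresholds achieve the FDR target; acceptance is empty"
            )
            break
        protein_fdr, protein_groups = protein_level_fdr(accepted, decoy_prefix)
        if protein_fdr <= target_fdr:
            break
        working /= 2.0
    else:
        diagnostics.append(
            f"protein FDR target {target_fdr} not reached in {max_rounds} rounds; "
            "acceptance is empty"
        )
        accepted = []

    protein_fdr, protein_groups = protein_level_fdr(accepted, decoy_prefix)
    # Proteins identified by a single distinct peptide are flagged for review.
    peptides_per_group: dict[frozenset[str], set[str]] = {g: set() for g in protein_groups}
    for p in accepted:
        for g in protein_groups:
            if set(p.protein_ids) & g:
                peptides_per_group[g].add(chem.format_flanked(p.peptide))
    single = [g for g, peps in peptides_per_group.items() if len(peps) == 1]

    return FilterResult(
        thresholds=thresholds,
        accepted=accepted,
        nd=sum(1 for p in accepted if p.is_decoy),
        nt=len(accepted),
        fdr_estimate=estimate_fdr(accepted),
        protein_fdr=protein_fdr,
        protein_groups=protein_groups,
        ppm_limit=ppm_limit,
        single_peptide_groups=single,
        rejected_charge=rejected,
        diagnostics=diagnostics,
    )
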