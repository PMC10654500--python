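"""Rule-based nomination of mutation sites and variant naming.

Three design criteria drive nomination:

1. Dissociation-class sites sit on the dissociating strand, face out of the
   barrel (or are solvent-exposed at the cleaved terminus), and either keep
   a sidechain interaction across strands in the pre-dissociation trans
   state or appear in the annealing anchor-loss order.
2. Isomerization-class sites contact the chromophore somewhere in the
   interior of the phi_I path (strictly between the cis and trans endpoint
   windows).
3. Sites whose mutation could affect *both* steps cannot be deconvolved
   experimentally and are flagged excluded: an isomerization site is
   excluded when it lies on the dissociating strand or itself interacts
   with the dissociating strand in either state.

Substitution proposals follow two modes: removing polar interactions
(alanine) or introducing steric clashes (bulky nonpolar residues).
Variants are named by the amino acids at the named strand positions from
N- to C-terminus ("YSK", "AAA", "IWI"), with a hyphen suffix for
off-strand additions ("IWI-A").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Data.IUPACData import protein_letters_3to1

from .errors import StrandgateError
from .hbond_network import Interaction, OccupancyTable, PathwayProfile
from .structure_core import StrandTopology

__all__ = [
    "NominationThresholds",
    "DesignEvidence",
    "MutationCandidate",
    "VariantName",
    "nominate",
    "propose_substitutions",
    "name_variant",
    "enumerate_combination_variants",
    "STERIC_CLASH_RESIDUES",
]

STERIC_CLASH_RESIDUES = ("ILE", "VAL", "LEU", "TRP")
_UNMUTABLE = {"GLY", "ALA", "PRO"}


@dataclass(frozen=True)
class NominationThresholds:
    """Occupancy thresholds; the trans threshold sits below the cis
    persistence default because the trans complex keeps fewer stable
    inter-strand interactions."""

    trans_occupancy_min: float = 0.3
    chromophore_contact_min: float = 0.05
    dual_occupancy_min: float = 0.3


@dataclass
class DesignEvidence:
    """Everything the nomination rules consume, all on one topology."""

    cis_occupancy: OccupancyTable
    trans_occupancy: OccupancyTable          # pre-dissociation segment
    pathway: PathwayProfile
    orientation: Mapping[int, str]           # residue -> in/out/exposed
    anchor_order: Sequence[tuple[Interaction, int]]
    residue_names: Mapping[int, str] = field(default_factory=dict)


@dataclass
class MutationCandidate:
    residue_number: int
    residue_name: str
    klass: str                               # "dissociation" | "isomerization"
    evidence_summary: dict
    rank: int = 0
    excluded: bool = False
    exclusion_reason: str | None = None


def _sc_interactions_of(table: OccupancyTable, residue: int,
                        min_occupancy: float) -> list[tuple[Interaction, float]]:
    return [(i, f) for i, f in table.fractions.items()
            if f >= min_occupancy and i.involves(residue, moiety="sc")]


def _interacts_with_strand(table: OccupancyTable, residue: int,
                           strand_residues: set[int], min_occupancy: float) -> bool:
    for interaction, occ in table.fractions.items():
        if occ < min_occupancy or not interaction.involves(residue):
            continue
        other = [r for r in interaction.residues if r != residue]
        if any(r in strand_residues for r in other):
            return True
    return False


def nominate(evidence: DesignEvidence, topo: StrandTopology,
             thresholds: NominationThresholds = NominationThresholds()
             ) -> list[MutationCandidate]:
    """Apply the three design criteria; returns candidates (excluded ones
    flagged, never silently dropped), dissociation class first, each class
    ranked (1 = strongest evidence)."""
    if not evidence.cis_occupancy.fractions and not evidence.trans_occupancy.fractions:
        raise StrandgateError("empty evidence: no interactions in either state")

    diss_residues = set(topo.residues_of(topo.dissociating_strand))
    names = evidence.residue_names
    anchor_position = {}
    for pos, (interaction, _) in enumerate(evidence.anchor_order):
        for p in (interaction.partner_a, interaction.partner_b):
            if p.moiety == "sc" and p.residue_number in diss_residues:
                anchor_position[p.residue_number] = max(
                    anchor_position.get(p.residue_number, -1), pos)

    # criterion 1: dissociation sites
    dissociation: dict[int, dict] = {}
    for res in sorted(diss_residues):
        if evidence.orientation.get(res) not in ("out", "exposed"):
            continue
        trans_sc = _sc_interactions_of(evidence.trans_occupancy, res,
                                       thresholds.trans_occupancy_min)
        in_anchor = res in anchor_position
        if not trans_sc and not in_anchor:
            continue
        dissociation[res] = {
            "orientation": evidence.orientation.get(res),
            "trans_interactions": sorted(
                (repr(i), occ) for i, occ in trans_sc),
            "trans_occupancy_sum": sum(occ for _, occ in trans_sc),
            "anchor_order_position": anchor_position.get(res),
        }

    # criterion 2: isomerization sites (interior phi_I windows only)
    interior = set(evidence.pathway.interior_centers.tolist())
    chromo = topo.chromophore_residues
    isomerization: dict[int, dict] = {}
    for idx, interaction in enumerate(evidence.pathway.interactions):
        if not any(r in chromo for r in interaction.residues):
            continue
        partners = [p for p in (interaction.partner_a, interaction.partner_b)
                    if p.residue_number not in chromo and p.moiety == "sc"]
        row = evidence.pathway.matrix[idx]
        hit_centers = [float(c) for c, occ in zip(evidence.pathway.centers, row)
                       if occ >= thresholds.chromophore_contact_min and float(c) in interior]
        if not hit_centers:
            continue
        for p in partners:
            info = isomerization.setdefault(p.residue_number, {
                "contact_windows_deg": [], "max_interior_occupancy": 0.0,
                "break_window_deg": evidence.pathway.break_points.get(interaction)})
            info["contact_windows_deg"] = sorted(
                set(info["contact_windows_deg"]) | set(hit_centers))
            info["max_interior_occupancy"] = max(
                info["max_interior_occupancy"],
                float(max(occ for c, occ in zip(evidence.pathway.centers, row)
                          if float(c) in interior)))

    candidates: list[MutationCandidate] = []

    diss_ranked = sorted(
        dissociation.items(),
        key=lambda kv: (-kv[1]["trans_occupancy_sum"],
                        -(kv[1]["anchor_order_position"] if
                          kv[1]["anchor_order_position"] is not None else -1),
                        kv[0]))
    for rank, (res, summary) in enumerate(diss_ranked, start=1):
        if res in isomerization:
            continue  # handled below as a dual-class exclusion
        candidates.append(MutationCandidate(
            res, names.get(res, "UNK"), "dissociation", summary, rank=rank))

    iso_ranked = sorted(isomerization.items(),
                        key=lambda kv: (-kv[1]["max_interior_occupancy"], kv[0]))
    rank = 0
    for res, summary in iso_ranked:
        reason = None
        if res in dissociation:
            reason = ("qualifies for both dissociation and isomerization; the "
                      "contribution of a mutation to each step cannot be untangled")
        elif res in diss_residues:
            reason = ("on the dissociating strand: isomerization precedes "
                      "strand-dissociation, so effects cannot be untangled")
        elif _interacts_with_strand(evidence.cis_occupancy, res, diss_residues,
                                    thresholds.dual_occupancy_min) or \
                _interacts_with_strand(evidence.trans_occupancy, res, diss_residues,
                                       thresholds.dual_occupancy_min):
            reason = ("interacts with the dissociating strand: effects on "
                      "isomerization and dissociation cannot be untangled")
        if reason is None:
            rank += 1
        candidates.append(MutationCandidate(
            res, names.get(res, "UNK"), "isomerization", summary,
            rank=0 if reason else rank,
            excluded=reason is not None, exclusion_reason=reason))
    return candidates


def propose_substitutions(candidate: MutationCandidate, mode: str
                          ) -> tuple[list[str], str | None]:
    """Amino acids to try at a site; mode "remove_polar" (alanine) or
    "steric_clash" (bulky nonpolar set).  Gly/Ala/Pro sites return an empty
    list with an explanatory note."""
    if candidate.excluded:
        raise StrandgateError(
            f"residue {candidate.residue_number} is excluded: "
            f"{candidate.exclusion_reason}")
    if candidate.residue_name.upper() in _UNMUTABLE:
        return [], (f"{candidate.residue_name}{candidate.residue_number}: no "
                    "polar sidechain interactions to remove at this site")
    if mode == "remove_polar":
        return ["ALA"], None
    if mode == "steric_clash":
        return list(STERIC_CLASH_RESIDUES), None
    raise ValueError(f"unknown substitution mode {mode!r}")


# ---------------------------------------------------------------------------
# variant naming
# ---------------------------------------------------------------------------

def _one_letter(aa: str) -> str:
    if len(aa) == 1:
        return aa.upper()
    try:
        return protein_letters_3to1[aa.capitalize()]
    except KeyError:
        raise StrandgateError(f"unknown amino acid {aa!r}") from None


@dataclass(frozen=True)
class VariantName:
    """Letters at the named on-strand positions (N->C), plus an optional
    hyphen suffix for off-strand additions."""

    on_strand: str
    suffix: str = ""

    @property
    def name(self) -> str:
        return f"{self.on_strand}-{self.suffix}" if self.suffix else self.on_strand

    def __str__(self) -> str:
        return self.name


def name_variant(named_positions: Sequence[tuple[int, str]],
                 mutations: Mapping[int, str] | None = None,
                 off_strand: Mapping[int, str] | None = None) -> VariantName:
    """Name a variant from (position, wild-type residue) pairs and mutations.

    >>> sites = [(200, "TYR"), (202, "SER"), (209, "LYS")]
    >>> name_variant(sites).name
    'YSK'
    >>> name_variant(sites, {200: "ALA", 202: "ALA", 209: "ALA"},
    ...              off_strand={121: "ALA"}).name
    'AAA-A'
    """
    mutations = dict(mutations or {})
    positions = [p for p, _ in named_positions]
    unknown = sorted(set(mutations) - set(positions))
    if unknown:
        raise StrandgateError(f"mutated positions not among named sites: {unknown}")
    ordered = sorted(named_positions, key=lambda pw: pw[0])
    letters = "".join(_one_letter(mutations.get(pos, wt)) for pos, wt in ordered)
    suffix = ""
    if off_strand:
        suffix = "".join(_one_letter(aa)
                         for _, aa in sorted(off_strand.items()))
    return VariantName(letters, suffix)


def enumerate_combination_variants(
    named_positions: Sequence[tuple[int, str]],
    site_substitutions: Mapping[int, Sequence[str]],
) -> list[VariantName]:
    """All 1-, 2-, ..., n-site combination variants over the named sites.

    Single-site effects compose unpredictably (a site useless alone can be
    essential in a triple), so the full combination set is emitted rather
    than single mutants only."""
    positions = sorted(site_substitutions)
    variants: list[VariantName] = []
    seen = set()
    for n_sites in range(1, len(positions) + 1):
        for subset in itertools.combinations(positions, n_sites):
            for choice in itertools.product(
                    *(site_substitutions[p] for p in subset)):
                variant = name_variant(named_positions, dict(zip(subset, choice)))
                if variant.name not in seen:
                    seen.add(variant.name)
                    variants.append(variant)
    return variants
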