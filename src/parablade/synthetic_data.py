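"""Synthetic paralog families and toy propeller structures.

The generator emulates the situation the detection rule targets: an
ancestral protein duplicated into two paralog clades carried by several
species, with (a) planted diagnostic sites — conserved within each clade
but divergent between clades, the divergent pair having a negative
substitution score and/or opposite charge — and (b) neutral background
substitutions sprinkled independently along each lineage (a star species
tree).  The generator is indel-free so every truth label refers
unambiguously to one alignment column.

``make_toy_structure`` lays out an n-bladed CA-only structure whose blades
are well-separated point clusters, so both the blade-count and the spatial
clustering statistics have signal when sites are planted in one blade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .divergence import residue_charge
from .seqio import STANDARD_AA, ProteinSequence, SubstitutionMatrix, load_blosum62
from .structmap import BladeAnnotation

MODE_BLOSUM = "blosum_negative"
MODE_CHARGE = "opposite_charge"
MODE_BOTH = "both"

DEFAULT_SPECIES = ["pombe", "octosporus", "japonicus"]
DEFAULT_CRITERION = ["pombe", "octosporus"]


@dataclass
class SimulationParams:
    """Study conditions for the paralog-family simulator.

    Defaults mirror the three-fission-yeast setting: two paralog groups
    across three species, the criterion evaluated on two of them, an
    outgroup included, 300-residue proteins with 10 diagnostic sites, a 5%
    per-site per-lineage neutral substitution probability and no
    within-group corruption.
    """

    n_species: int = 3
    species: list[str] = field(default_factory=lambda: list(DEFAULT_SPECIES))
    criterion_species: list[str] = field(default_factory=lambda: list(DEFAULT_CRITERION))
    group_a: str = "Tup11"
    group_b: str = "Tup12"
    length: int = 300
    n_diagnostic_sites: int = 10
    mode: str = MODE_BOTH
    theta: float = 0.05
    epsilon: float = 0.0
    include_outgroup: bool = True
    seed: int = 0
    #: optional 1-based positions from which diagnostic sites are drawn
    #: (e.g. one blade's range, to plant a spatial cluster); None = anywhere
    position_pool: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if len(self.species) != self.n_species:
            raise ValueError("species list length must equal n_species")
        if not set(self.criterion_species) <= set(self.species):
            raise ValueError("criterion species must be a subset of species")
        if not 0 <= self.theta < 1 or not 0 <= self.epsilon < 1:
            raise ValueError("theta and epsilon must lie in [0, 1)")
        if self.n_diagnostic_sites > self.length:
            raise ValueError("more diagnostic sites than positions")
        if self.position_pool is not None:
            if len(set(self.position_pool)) < self.n_diagnostic_sites:
                raise ValueError("position pool smaller than n_diagnostic_sites")
            if not all(1 <= p <= self.length for p in self.position_pool):
                raise ValueError("position pool outside 1..length")
        if self.mode not in (MODE_BLOSUM, MODE_CHARGE, MODE_BOTH):
            raise ValueError(f"unknown diagnostic mode {self.mode!r}")


@dataclass
class SyntheticFamily:
    """Simulated sequences plus ground-truth diagnostic-site labels."""

    sequences: list[ProteinSequence]
    truth: list[tuple[int, str, str, str]]  # (position 1-based, res_a, res_b, mode)
    params: SimulationParams

    @property
    def outgroup_id(self) -> Optional[str]:
        for s in self.sequences:
            if s.group == "outgroup":
                return s.id
        return None

    def truth_positions(self) -> list[int]:
        return sorted(p for p, _, _, _ in self.truth)


def _mode_ok(a: str, b: str, mode: str, matrix: SubstitutionMatrix) -> bool:
    if a == b:
        return False
    neg = matrix.score(a, b) < 0
    opp = residue_charge(a) * residue_charge(b) == -1
    if mode == MODE_BLOSUM:
        return neg
    if mode == MODE_CHARGE:
        return opp
    return neg and opp


def _diagnostic_pairs(mode: str, matrix: SubstitutionMatrix
                      ) -> dict[str, list[str]]:
    """Partners b for each residue a such that (a, b) satisfies *mode*."""
    table: dict[str, list[str]] = {}
    for a in STANDARD_AA:
        partners = [b for b in STANDARD_AA if _mode_ok(a, b, mode, matrix)]
        if partners:
            table[a] = partners
    if not table:
        raise ValueError(f"no residue pair satisfies mode {mode!r}")
    return table


def simulate_paralog_families(params: SimulationParams,
                              matrix: Optional[SubstitutionMatrix] = None
                              ) -> SyntheticFamily:
    """Simulate two paralog clades with planted diagnostic sites.

    The ancestor is uniform over the 20 residues.  At each diagnostic
    position clade A carries a residue admitting a partner under the
    requested mode (the ancestral residue where possible) and clade B the
    sampled partner.  Neutral substitutions hit non-diagnostic positions of
    every lineage independently with probability ``theta``; with
    probability ``epsilon`` a criterion-species row is corrupted at a
    diagnostic site, breaking within-group identity.  Fully deterministic
    given ``params.seed``.
    """
    matrix = matrix or load_blosum62()
    rng = np.random.default_rng(params.seed)
    aa = np.array(list(STANDARD_AA))
    L = params.length
    ancestor = rng.choice(aa, size=L).tolist()

    pairs = _diagnostic_pairs(params.mode, matrix)
    eligible_a = sorted(pairs)
    if params.position_pool is not None:
        pool0 = np.array(sorted({p - 1 for p in params.position_pool}))
    else:
        pool0 = np.arange(L)
    positions = sorted(rng.choice(pool0, size=params.n_diagnostic_sites,
                                  replace=False).tolist())
    truth = []
    res_a_at = {}
    res_b_at = {}
    for pos in positions:
        a = ancestor[pos]
        if a not in pairs:
            a = str(rng.choice(eligible_a))
        b = str(rng.choice(pairs[a]))
        res_a_at[pos], res_b_at[pos] = a, b
        truth.append((pos + 1, a, b, params.mode))
    diagnostic = set(positions)

    def lineage(base: list[str]) -> list[str]:
        """Apply neutral substitutions off the diagnostic sites."""
        out = list(base)
        hits = np.nonzero(rng.random(L) < params.theta)[0]
        for pos in hits:
            if pos in diagnostic:
                continue
            alternatives = [c for c in STANDARD_AA if c != out[pos]]
            out[pos] = str(rng.choice(np.array(alternatives)))
        return out

    base_a = list(ancestor)
    base_b = list(ancestor)
    for pos in positions:
        base_a[pos] = res_a_at[pos]
        base_b[pos] = res_b_at[pos]

    sequences = []
    for group, base in ((params.group_a, base_a), (params.group_b, base_b)):
        for species in params.species:
            row = lineage(base)
            if params.epsilon > 0 and species in params.criterion_species:
                for pos in positions:
                    if rng.random() < params.epsilon:
                        alternatives = [c for c in STANDARD_AA if c != row[pos]]
                        row[pos] = str(rng.choice(np.array(alternatives)))
            sequences.append(ProteinSequence(
                id=f"{species}_{group}", residues="".join(row),
                species=species, group=group))
    if params.include_outgroup:
        row = lineage(list(ancestor))
        sequences.append(ProteinSequence(
            id="outgroup_ref", residues="".join(row),
            species="outgroup", group="outgroup"))
    return SyntheticFamily(sequences=sequences, truth=truth, params=params)


def family_group_spec(family: SyntheticFamily):
    """The :class:`~parablade.divergence.GroupSpec` matching a simulation."""
    from .divergence import GroupSpec

    p = family.params
    return GroupSpec(
        group_a=p.group_a, group_b=p.group_b,
        members_a={sp: f"{sp}_{p.group_a}" for sp in p.species},
        members_b={sp: f"{sp}_{p.group_b}" for sp in p.species},
        criterion_species=list(p.criterion_species),
        outgroup_id=family.outgroup_id,
    )


def write_truth_tsv(family: SyntheticFamily, handle) -> None:
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_truth_tsv(family, fh)
            return
    handle.write("position\tresidue_a\tresidue_b\tmode\n")
    for pos, a, b, mode in family.truth:
        handle.write(f"{pos}\t{a}\t{b}\t{mode}\n")


def make_toy_structure(n_blades: int = 7, residues_per_blade: int = 10,
                       start_number: int = 301,
                       missing_spans: Optional[Sequence[tuple[int, int]]] = None,
                       chain: str = "A"
                       ) -> tuple[str, BladeAnnotation]:
    """Generate CA-only PDB text with blades as well-separated clusters.

    Blade centroids sit on a wide circle (spacing >= 10x the intra-blade
    spread) so that sites planted in one blade are spatially close.
    Residues inside ``missing_spans`` (inclusive, author numbering) are
    omitted from the coordinates, emulating disordered regions.  Returns
    the PDB text and the matching blade annotation.
    """
    if n_blades < 1:
        raise ValueError("need at least one blade")
    end_number = start_number + n_blades * residues_per_blade - 1
    missing: set[int] = set()
    for lo, hi in (missing_spans or ()):
        if lo < start_number or hi > end_number or hi < lo:
            raise ValueError(f"missing span {lo}-{hi} outside {start_number}-{end_number}")
        missing.update(range(lo, hi + 1))

    spread = 2.0
    ring_radius = max(40.0, 10.0 * spread * n_blades / (2 * math.pi) * 4)
    lines = []
    serial = 1
    annotation_ranges = []
    number = start_number
    for blade in range(1, n_blades + 1):
        angle = 2 * math.pi * (blade - 1) / n_blades
        cx, cy = ring_radius * math.cos(angle), ring_radius * math.sin(angle)
        first = number
        for k in range(residues_per_blade):
            phi = 2 * math.pi * k / max(residues_per_blade, 1)
            x = cx + spread * math.cos(phi)
            y = cy + spread * math.sin(phi)
            z = 0.5 * (k % 3)
            if number not in missing:
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA {chain}{number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
                serial += 1
            number += 1
        annotation_ranges.append((blade, "A", first, number - 1))
    lines.append("TER")
    lines.append("END")
    annotation = BladeAnnotation(annotation_ranges, n_blades=n_blades)
    return "\n".join(lines) + "\n", annotation
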