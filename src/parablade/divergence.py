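"""Group-diagnostic divergent-residue detection.

A divergent site is an alignment column where each paralog group carries
one conserved residue (checked over a designated set of criterion species),
the two group residues differ, and the difference is a significant property
change: a negative substitution-matrix score or opposite net charge.
Reported sites are then polarized against an outgroup sequence, recording
which group (if either) retains the outgroup residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .seqio import GAP, MultipleAlignment, SubstitutionMatrix

#: net side-chain charge at physiological pH; histidine is treated as
#: neutral by default because its protonation is pH-dependent.
CHARGE_TABLE = {"D": -1, "E": -1, "K": +1, "R": +1}

CATEGORY_BOTH_DIFFER = "both_differ"
CATEGORY_A_MATCHES = "A_matches_outgroup"
CATEGORY_B_MATCHES = "B_matches_outgroup"
CATEGORY_UNCLASSIFIED = "unclassified"

REASON_BLOSUM = "blosum_negative"
REASON_CHARGE = "opposite_charge"


def residue_charge(aa: str, histidine_positive: bool = False) -> int:
    """Net charge sign of a residue: D,E -> -1; K,R -> +1; others 0.

    ``histidine_positive`` optionally treats H as +1.
    """
    from .seqio import ALPHABET

    if aa not in ALPHABET:
        raise ValueError(f"invalid residue letter {aa!r}")
    if histidine_positive and aa == "H":
        return +1
    return CHARGE_TABLE.get(aa, 0)


def is_significant_pair(r1: str, r2: str, matrix: SubstitutionMatrix,
                        histidine_positive: bool = False
                        ) -> tuple[bool, frozenset[str]]:
    """Whether two differing residues have significantly different properties.

    True iff their substitution score is negative or their charges are
    opposite.  The reason set records which clause(s) fired.  Identical
    residues are a caller error: the predicate is only defined on differing
    pairs.
    """
    if r1 == r2:
        raise ValueError(f"is_significant_pair requires differing residues, got {r1!r} twice")
    reasons = set()
    if matrix.score(r1, r2) < 0:
        reasons.add(REASON_BLOSUM)
    if residue_charge(r1, histidine_positive) * residue_charge(r2, histidine_positive) == -1:
        reasons.add(REASON_CHARGE)
    return bool(reasons), frozenset(reasons)


@dataclass
class GroupSpec:
    """Two paralog groups, their members per species, and the outgroup.

    ``members_a``/``members_b`` map species label -> sequence id.  The
    divergence criterion is evaluated only on ``criterion_species`` (the
    species whose group-B proteins functionally substitute for each other);
    other species' rows are carried in the alignment but do not gate the
    within-group conservation requirement.
    """

    group_a: str
    group_b: str
    members_a: dict[str, str]
    members_b: dict[str, str]
    criterion_species: list[str]
    outgroup_id: Optional[str] = None

    def __post_init__(self) -> None:
        ids_a = set(self.members_a.values())
        ids_b = set(self.members_b.values())
        if ids_a & ids_b:
            raise ValueError("paralog groups share sequence ids")
        if not self.criterion_species:
            raise ValueError("criterion species set is empty")
        for sp in self.criterion_species:
            if sp not in self.members_a or sp not in self.members_b:
                raise ValueError(f"criterion species {sp!r} missing from a group")
        if self.outgroup_id is not None and self.outgroup_id in ids_a | ids_b:
            raise ValueError("outgroup cannot be a group member")

    @property
    def criterion_ids_a(self) -> list[str]:
        return [self.members_a[sp] for sp in self.criterion_species]

    @property
    def criterion_ids_b(self) -> list[str]:
        return [self.members_b[sp] for sp in self.criterion_species]

    @property
    def all_ids(self) -> list[str]:
        ids = list(self.members_a.values()) + list(self.members_b.values())
        if self.outgroup_id:
            ids.append(self.outgroup_id)
        return ids


@dataclass
class DivergentSite:
    """One alignment column flagged by the divergence rule."""

    column: int
    residue_a: str
    residue_b: str
    blosum_score: int
    charge_a: int
    charge_b: int
    significant_by: frozenset[str]
    category: str = CATEGORY_UNCLASSIFIED
    structure_residue: Optional[int] = None
    blade: Optional[int] = None
    disordered: bool = False

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("divergent site with identical group residues")
        if not self.significant_by:
            raise ValueError("divergent site with empty reason set")


def _conserved_residue(msa: MultipleAlignment, ids: Sequence[str], col: int
                       ) -> Optional[str]:
    """The single residue shared by all rows at a column, else None.

    Gaps and 'X' disqualify the column: identity cannot be certified.
    """
    residues = {msa.row(i)[col - 1] for i in ids}
    if len(residues) != 1:
        return None
    (r,) = residues
    if r == GAP or r == "X":
        return None
    return r


def find_divergent_sites(msa: MultipleAlignment, spec: GroupSpec,
                         matrix: SubstitutionMatrix,
                         histidine_positive: bool = False
                         ) -> list[DivergentSite]:
    """Scan alignment columns for group-diagnostic divergent residues.

    A column is reported iff all criterion-species rows of group A agree on
    one residue, all of group B agree on another, the two differ, and
    :func:`is_significant_pair` holds.  Columns with a gap or ambiguity in
    any criterion row are skipped.
    """
    for seq_id in spec.criterion_ids_a + spec.criterion_ids_b:
        msa.row(seq_id)  # raises KeyError if missing
    sites = []
    for col in range(1, msa.length + 1):
        ra = _conserved_residue(msa, spec.criterion_ids_a, col)
        if ra is None:
            continue
        rb = _conserved_residue(msa, spec.criterion_ids_b, col)
        if rb is None or ra == rb:
            continue
        significant, reasons = is_significant_pair(ra, rb, matrix, histidine_positive)
        if not significant:
            continue
        sites.append(DivergentSite(
            column=col, residue_a=ra, residue_b=rb,
            blosum_score=matrix.score(ra, rb),
            charge_a=residue_charge(ra, histidine_positive),
            charge_b=residue_charge(rb, histidine_positive),
            significant_by=reasons,
        ))
    return sites


def classify_vs_outgroup(sites: Sequence[DivergentSite], msa: MultipleAlignment,
                         outgroup_id: str) -> list[DivergentSite]:
    """Polarize sites against the outgroup residue at each column.

    Outgroup equals group A's residue -> ``A_matches_outgroup``; equals
    group B's -> ``B_matches_outgroup``; differs from both ->
    ``both_differ``; outgroup gapped -> ``unclassified``.
    """
    row = msa.row(outgroup_id)  # KeyError if absent
    out = []
    for site in sites:
        ro = row[site.column - 1]
        if ro == GAP:
            category = CATEGORY_UNCLASSIFIED
        elif ro == site.residue_a:
            category = CATEGORY_A_MATCHES
        elif ro == site.residue_b:
            category = CATEGORY_B_MATCHES
        else:
            category = CATEGORY_BOTH_DIFFER
        out.append(replace(site, category=category))
    return out


def sites_to_frame(sites: Sequence[DivergentSite]) -> pd.DataFrame:
    """Long-form site table ready for TSV export."""
    rows = []
    for s in sites:
        rows.append({
            "alignment_column": s.column,
            "residue_a": s.residue_a,
            "residue_b": s.residue_b,
            "blosum_score": s.blosum_score,
            "charge_a": s.charge_a,
            "charge_b": s.charge_b,
            "reasons": "+".join(sorted(s.significant_by)),
            "category": s.category,
            "structure_residue": "" if s.structure_residue is None else s.structure_residue,
            "blade": "" if s.blade is None else s.blade,
            "disordered": int(s.disordered),
        })
    return pd.DataFrame(rows, columns=[
        "alignment_column", "residue_a", "residue_b", "blosum_score",
        "charge_a", "charge_b", "reasons", "category", "structure_residue",
        "blade", "disordered",
    ])
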