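"""Mapping divergent alignment columns onto a reference structure and
testing whether they cluster on particular propeller blades.

The reference row of the alignment is walked residue by residue: its k-th
non-gap position corresponds to author residue number ``ref_start + k - 1``
of the intact reference protein.  Sites landing on residues absent from the
crystal coordinates are flagged disordered; they still count toward blade
occupancy but are excluded from the spatial statistic.

Clustering is assessed against a permutation null that re-draws the same
number of sites uniformly without replacement from the eligible residues.
When the eligible set is small the null is enumerated exhaustively;
otherwise it is sampled Monte-Carlo with an add-one correction so the
p-value can never be zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .divergence import DivergentSite, sites_to_frame
from .seqio import GAP, MultipleAlignment, StructureModel, write_attribute_map

STAT_MAX_BLADE = "max_blade_count"
STAT_MEAN_DIST = "mean_pairwise_ca_distance"

#: exhaustive enumeration is used when the null has at most this many draws
EXHAUSTIVE_LIMIT = 100_000


@dataclass
class BladeAnnotation:
    """Strand residue ranges of an n-bladed propeller, reference numbering."""

    ranges: list[tuple[int, str, int, int]]  # (blade, strand, first, last)
    n_blades: int = 7

    def __post_init__(self) -> None:
        blades = sorted({b for b, _, _, _ in self.ranges})
        if blades != list(range(1, len(blades) + 1)):
            raise ValueError("blade indices must be contiguous from 1")
        if blades and blades[-1] > self.n_blades:
            raise ValueError("blade index exceeds n_blades")
        spans = sorted((first, last) for _, _, first, last in self.ranges)
        for (f1, l1), (f2, l2) in zip(spans, spans[1:]):
            if f2 <= l1:
                raise ValueError(f"overlapping ranges {f1}-{l1} and {f2}-{l2}")

    def blade_of(self, residue: int) -> Optional[int]:
        for blade, _, first, last in self.ranges:
            if first <= residue <= last:
                return blade
        return None

    @property
    def annotated_residues(self) -> list[int]:
        out: set[int] = set()
        for _, _, first, last in self.ranges:
            out.update(range(first, last + 1))
        return sorted(out)


def read_blade_annotation(handle, n_blades: Optional[int] = None) -> BladeAnnotation:
    """Read a blade annotation TSV: columns blade, strand, start, end."""
    if isinstance(handle, str) or isinstance(handle, Path):
        with open(handle) as fh:
            return read_blade_annotation(fh, n_blades)
    ranges = []
    header = True
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header:
            header = False
            continue
        blade, strand, start, end = line.split("\t")
        ranges.append((int(blade), strand, int(start), int(end)))
    nb = n_blades or max(b for b, _, _, _ in ranges)
    return BladeAnnotation(ranges, n_blades=nb)


def default_blade_annotation() -> BladeAnnotation:
    """The packaged default seven-blade annotation."""
    text = resources.files("parablade.data").joinpath("wd40_blades.tsv").read_text()
    import io

    return read_blade_annotation(io.StringIO(text))


@dataclass
class ColumnResidueMap:
    """Alignment column -> (reference residue number, disordered flag)."""

    mapping: dict[int, tuple[int, bool]]

    def __post_init__(self) -> None:
        cols = sorted(self.mapping)
        nums = [self.mapping[c][0] for c in cols]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise ValueError("mapped residue numbers must increase with column")

    def residue(self, column: int) -> Optional[int]:
        entry = self.mapping.get(column)
        return entry[0] if entry else None

    def disordered(self, column: int) -> bool:
        entry = self.mapping.get(column)
        return bool(entry and entry[1])


def map_alignment_to_structure(msa: MultipleAlignment, ref_id: str,
                               ref_start: int, structure: StructureModel
                               ) -> ColumnResidueMap:
    """Map alignment columns to reference residue numbers.

    ``ref_start`` is the author number of the first non-gap residue of the
    reference row (282 for the Tup1 WD40 alignment).  Disorder flags are
    copied from the structure.
    """
    row = msa.row(ref_id)
    lo, hi = structure.seq_span
    mapping: dict[int, tuple[int, bool]] = {}
    k = 0
    for col, char in enumerate(row, start=1):
        if char == GAP:
            continue
        number = ref_start + k
        k += 1
        if not lo <= number <= hi:
            raise ValueError(
                f"mapped residue {number} outside structure span {lo}-{hi}"
            )
        mapping[col] = (number, structure.residue(number).disordered)
    return ColumnResidueMap(mapping)


def map_sites(sites: Sequence[DivergentSite], colmap: ColumnResidueMap,
              annotation: Optional[BladeAnnotation] = None
              ) -> list[DivergentSite]:
    """Attach structure residue numbers (and blades) to divergent sites.

    Sites whose column is unmapped (reference row gapped there) are kept
    with no structure residue.
    """
    out = []
    for site in sites:
        number = colmap.residue(site.column)
        blade = annotation.blade_of(number) if (annotation and number) else None
        out.append(replace(site, structure_residue=number,
                           blade=blade,
                           disordered=colmap.disordered(site.column)))
    return out


def blade_count_profile(sites: Sequence[DivergentSite],
                        annotation: BladeAnnotation
                        ) -> tuple[list[int], int]:
    """Number of mapped sites per blade, plus the unassigned (loop) count."""
    counts = [0] * annotation.n_blades
    unassigned = 0
    for site in sites:
        if site.structure_residue is None:
            unassigned += 1
            continue
        blade = annotation.blade_of(site.structure_residue)
        if blade is None:
            unassigned += 1
        else:
            counts[blade - 1] += 1
    return counts, unassigned


@dataclass
class ClusteringResult:
    """Observed clustering statistic and its permutation p-value."""

    statistic: str
    observed: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def _max_blade_count(residues: Sequence[int], annotation: BladeAnnotation) -> float:
    counts = [0] * annotation.n_blades
    for r in residues:
        blade = annotation.blade_of(r)
        if blade is not None:
            counts[blade - 1] += 1
    return float(max(counts)) if counts else 0.0


def clustering_test(sites: Sequence[DivergentSite], structure: StructureModel,
                    annotation: BladeAnnotation,
                    statistic: str = STAT_MAX_BLADE,
                    n_permutations: int = 10_000,
                    seed: Optional[int] = None,
                    eligible: Optional[Sequence[int]] = None
                    ) -> ClusteringResult:
    """Permutation test for spatial clustering of mapped divergent sites.

    ``max_blade_count`` (upper tail) asks whether one blade holds more
    sites than expected; its null draws from all annotated residues and
    disordered sites participate.  ``mean_pairwise_ca_distance`` (lower
    tail) asks whether sites sit closer in space than random residues; its
    null draws from all resolved residues and disordered sites are dropped.

    The null enumerates all residue subsets when there are at most
    ``EXHAUSTIVE_LIMIT`` of them (p = m/N, exact); otherwise it samples
    ``n_permutations`` draws and applies the add-one correction
    p = (1 + hits) / (1 + n).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if statistic == STAT_MAX_BLADE:
        site_residues = [s.structure_residue for s in sites
                         if s.structure_residue is not None]
        pool = list(eligible) if eligible is not None else annotation.annotated_residues
        observed = _max_blade_count(site_residues, annotation)

        def stat(numbers: Sequence[int]) -> float:
            return _max_blade_count(numbers, annotation)

        upper_tail = True
    elif statistic == STAT_MEAN_DIST:
        site_residues = [s.structure_residue for s in sites
                         if s.structure_residue is not None and not s.disordered]
        pool = list(eligible) if eligible is not None else structure.resolved_numbers
        coords = {n: np.asarray(structure.residue(n).ca_xyz) for n in pool}
        for r in site_residues:
            if r not in coords:
                coords[r] = np.asarray(structure.residue(r).ca_xyz)

        def stat(numbers: Sequence[int]) -> float:
            pts = np.vstack([coords[n] for n in numbers])
            return float(pdist(pts).mean())

        observed = stat(site_residues) if len(site_residues) >= 2 else math.nan
        upper_tail = False
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    k = len(site_residues)
    if k < 2:
        raise ValueError("clustering test needs at least 2 mapped sites")
    if k > len(pool):
        raise ValueError("more sites than eligible residues")

    n_subsets = math.comb(len(pool), k)
    if n_subsets <= EXHAUSTIVE_LIMIT:
        null = [stat(subset) for subset in combinations(pool, k)]
        if upper_tail:
            hits = sum(1 for v in null if v >= observed - 1e-12)
        else:
            hits = sum(1 for v in null if v <= observed + 1e-12)
        p = hits / len(null)
        return ClusteringResult(statistic, observed, p, len(null), seed, True)

    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool)
    hits = 0
    for _ in range(n_permutations):
        draw = rng.choice(pool_arr, size=k, replace=False)
        v = stat(draw.tolist())
        if upper_tail:
            hits += v >= observed - 1e-12
        else:
            hits += v <= observed + 1e-12
    p = (1 + hits) / (1 + n_permutations)
    return ClusteringResult(statistic, observed, p, n_permutations, seed, False)


def report_divergence_map(sites: Sequence[DivergentSite],
                          annotation: BladeAnnotation,
                          out_dir, logger=None,
                          header_lines: Sequence[str] = ()) -> dict[str, str]:
    """Write the joined site table, viewer attribute file and blade summary.

    Sites on disordered residues are kept (flagged) in the site table but
    omitted from the attribute file, since a viewer cannot colour residues
    that have no coordinates.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = "".join(f"# {line}\n" for line in header_lines)

    site_path = out / "divergent_sites.tsv"
    frame = sites_to_frame(sites)
    with open(site_path, "w") as fh:
        fh.write(prefix)
        frame.to_csv(fh, sep="\t", index=False)

    attr_path = out / "divergent_sites.attr.tsv"
    attr_sites = [(s.structure_residue, s.category) for s in sites
                  if s.structure_residue is not None and not s.disordered]
    with open(attr_path, "w") as fh:
        fh.write(prefix)
        write_attribute_map(attr_sites, fh)

    summary_path = out / "blade_summary.tsv"
    counts, unassigned = blade_count_profile(sites, annotation)
    with open(summary_path, "w") as fh:
        fh.write(prefix)
        fh.write("blade\tn_divergent_sites\n")
        for blade, count in enumerate(counts, start=1):
            fh.write(f"{blade}\t{count}\n")
        fh.write(f"unassigned\t{unassigned}\n")

    if logger is not None:
        logger.info("wrote %s (%d sites)", site_path, len(sites))
        logger.info("wrote %s (%d residues)", attr_path, len(attr_sites))
        logger.info("wrote %s (%d blades)", summary_path, len(counts))
    return {"sites": str(site_path), "attributes": str(attr_path),
            "blade_summary": str(summary_path)}
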