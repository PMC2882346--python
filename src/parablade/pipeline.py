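"""End-to-end pipeline: tree, domain identities, MSA, divergent sites,
structure mapping and the clustering test, driven by one YAML config.

Every tabular output starts with comment lines recording the tool version,
a SHA-256 hash of the resolved config and the seed; formats that do not
tolerate comment lines (FASTA, newick, Clustal) are covered by the
MANIFEST.tsv written alongside, which lists the same provenance for every
artifact.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .align_phylo import (AlignmentParams, DomainPartition, build_distance_matrix,
                          domain_identity_matrix, nj_tree, progressive_msa)
from .divergence import GroupSpec, classify_vs_outgroup, find_divergent_sites
from .seqio import (MultipleAlignment, ProteinSequence, load_blosum62,
                    read_fasta, read_structure, read_substitution_matrix)
from .structmap import (clustering_test, default_blade_annotation, map_sites,
                        map_alignment_to_structure, read_blade_annotation,
                        report_divergence_map)

log = logging.getLogger("parablade")

EXIT_MISSING_FILE = 2
EXIT_BAD_GROUPSPEC = 3


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    fasta: str
    outdir: str
    groups: dict[str, Any]
    matrix: Optional[str] = None
    structure: Optional[dict[str, Any]] = None
    blade_annotation: Optional[str] = None
    domains: Optional[str] = None
    segments: Optional[str] = None
    reference: Optional[dict[str, Any]] = None
    alignment: dict[str, Any] = field(default_factory=dict)
    clustering: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"config file not found: {path}", EXIT_MISSING_FILE)
        with open(p) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, base_dir=p.parent)

    @classmethod
    def from_dict(cls, data: dict[str, Any], base_dir: Optional[Path] = None
                  ) -> "PipelineConfig":
        base = base_dir or Path(".")

        def resolve(value: Optional[str]) -> Optional[str]:
            if value is None:
                return None
            q = Path(value)
            return str(q) if q.is_absolute() else str(base / q)

        cfg = cls(
            fasta=resolve(data.get("fasta")) or "",
            outdir=resolve(data.get("outdir", "parablade_out")),
            groups=data.get("groups", {}),
            matrix=resolve(data.get("matrix")),
            structure=data.get("structure"),
            blade_annotation=resolve(data.get("blade_annotation")),
            domains=resolve(data.get("domains")),
            segments=resolve(data.get("segments")),
            reference=data.get("reference"),
            alignment=data.get("alignment", {}),
            clustering=data.get("clustering", {}),
            seed=int(data.get("seed", 0)),
            raw=data,
        )
        if cfg.structure and "path" in cfg.structure:
            cfg.structure = dict(cfg.structure)
            cfg.structure["path"] = resolve(cfg.structure["path"])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.fasta:
            raise PipelineError("config missing 'fasta' path", EXIT_MISSING_FILE)
        for label, path in [("fasta", self.fasta), ("matrix", self.matrix),
                            ("domains", self.domains), ("segments", self.segments),
                            ("blade_annotation", self.blade_annotation),
                            ("structure", (self.structure or {}).get("path"))]:
            if path is not None and not Path(path).exists():
                raise PipelineError(f"{label} file not found: {path}",
                                    EXIT_MISSING_FILE)
        if not self.groups:
            raise PipelineError("config missing 'groups' section", EXIT_BAD_GROUPSPEC)

    def group_spec(self) -> GroupSpec:
        g = self.groups
        try:
            return GroupSpec(
                group_a=g.get("group_a", "A"),
                group_b=g.get("group_b", "B"),
                members_a=dict(g["members_a"]),
                members_b=dict(g["members_b"]),
                criterion_species=list(g["criterion_species"]),
                outgroup_id=g.get("outgroup_id"),
            )
        except (KeyError, ValueError) as exc:
            raise PipelineError(f"invalid groups section: {exc}", EXIT_BAD_GROUPSPEC)

    def alignment_params(self, matrix) -> AlignmentParams:
        return AlignmentParams(
            matrix=matrix,
            gap_open=float(self.alignment.get("gap_open", 10.0)),
            gap_extend=float(self.alignment.get("gap_extend", 0.5)),
        )

    def config_hash(self) -> str:
        # the output location is not an analysis input
        payload = {k: v for k, v in self.raw.items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _read_segments(path: str) -> dict[str, tuple[int, int]]:
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#") or (i == 0 and not line.split("\t")[1].isdigit()):
                continue
            name, start, end = line.split("\t")
            out[name] = (int(start), int(end))
    return out


def _read_partitions(path: str) -> dict[str, DomainPartition]:
    table: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            protein, domain, start, end = line.split("\t")
            table.setdefault(protein, []).append((domain, int(start), int(end)))
    return {p: DomainPartition(r) for p, r in table.items()}


def _write_clustal(msa: MultipleAlignment, path: Path) -> None:
    width = 60
    with open(path, "w") as fh:
        fh.write("CLUSTAL W multiple sequence alignment\n\n")
        name_w = max(len(i) for i in msa.ids) + 3
        for start in range(0, msa.length, width):
            for seq_id, row in msa.rows:
                fh.write(f"{seq_id:<{name_w}}{row[start:start + width]}\n")
            fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage, write artifacts to ``config.outdir``.

    Returns a mapping of artifact names to paths.  Raises
    :class:`PipelineError` with the documented exit codes on failure;
    partial outputs are retained and MANIFEST.tsv notes incompleteness.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"parablade {__version__}",
        f"config_sha256 {config.config_hash()}",
        f"seed {config.seed}",
    ]
    prefix = "".join(f"# {line}\n" for line in header)
    artifacts: dict[str, str] = {}
    complete = False
    try:
        seqs = read_fasta(config.fasta)
        by_id = {s.id: s for s in seqs}
        matrix = (read_substitution_matrix(config.matrix, name=Path(config.matrix).stem)
                  if config.matrix else load_blosum62())
        params = config.alignment_params(matrix)
        spec = config.group_spec()
        missing = [i for i in spec.all_ids if i not in by_id]
        if missing:
            raise PipelineError(
                f"group members absent from FASTA: {', '.join(missing)}",
                EXIT_BAD_GROUPSPEC)
        log.info("read %d sequences from %s", len(seqs), config.fasta)

        # --- tree on full-length sequences
        if len(seqs) >= 3:
            dm = build_distance_matrix(
                seqs, params, model=config.alignment.get("distance_model", "identity"))
            tree = nj_tree(dm, outgroup=spec.outgroup_id)
            tree_path = out / "tree.nwk"
            tree_path.write_text(tree.newick() + "\n")
            artifacts["tree"] = str(tree_path)
            log.info("wrote %s (%d leaves)", tree_path, len(dm))

        # --- domain-wise identity matrix
        if config.domains:
            partitions = _read_partitions(config.domains)
            usable = [s for s in seqs if s.id in partitions]
            if len(usable) >= 2:
                dim = domain_identity_matrix(usable, partitions, params)
                ident_path = out / "domain_identity.tsv"
                with open(ident_path, "w") as fh:
                    fh.write(prefix)
                    dim.to_frame().to_csv(fh, sep="\t", index=False,
                                          float_format="%.1f")
                artifacts["domain_identity"] = str(ident_path)
                log.info("wrote %s (%d proteins)", ident_path, len(usable))

        # --- multiple alignment (optionally of configured segments)
        msa_input = seqs
        if config.segments:
            segments = _read_segments(config.segments)
            msa_input = []
            for s in seqs:
                if s.id in segments:
                    lo, hi = segments[s.id]
                    msa_input.append(ProteinSequence(
                        id=s.id, residues=s.residues[lo - 1:hi],
                        species=s.species, group=s.group))
                else:
                    msa_input.append(s)
        msa = progressive_msa(msa_input, params)
        afa_path = out / "msa.afa"
        with open(afa_path, "w") as fh:
            for seq_id, row in msa.rows:
                fh.write(f">{seq_id}\n{row}\n")
        _write_clustal(msa, out / "msa.aln")
        artifacts["msa_fasta"] = str(afa_path)
        artifacts["msa_clustal"] = str(out / "msa.aln")
        log.info("aligned %d sequences, %d columns", len(msa.rows), msa.length)

        # --- divergent sites
        sites = find_divergent_sites(
            msa, spec, matrix,
            histidine_positive=bool(config.raw.get("histidine_positive", False)))
        if spec.outgroup_id:
            sites = classify_vs_outgroup(sites, msa, spec.outgroup_id)
        log.info("found %d divergent sites", len(sites))

        # --- structure mapping and clustering
        annotation = None
        structure = None
        if config.blade_annotation:
            annotation = read_blade_annotation(config.blade_annotation)
        if config.structure:
            sc = config.structure
            if not sc.get("seq_span"):
                raise PipelineError("structure section requires a seq_span")
            span = tuple(sc["seq_span"])
            structure = read_structure(sc["path"], chain=sc.get("chain", "A"),
                                       seq_span=span, source=sc["path"])
            ref = config.reference or {}
            ref_id = ref.get("id", spec.outgroup_id)
            ref_start = int(ref.get("start", span[0]))
            colmap = map_alignment_to_structure(msa, ref_id, ref_start, structure)
            sites = map_sites(sites, colmap, annotation or default_blade_annotation())

        ann = annotation or default_blade_annotation()
        paths = report_divergence_map(sites, ann, out, logger=log,
                                      header_lines=header)
        artifacts.update(paths)

        if structure is not None and len(
                [s for s in sites if s.structure_residue is not None]) >= 2:
            cl = config.clustering
            result = clustering_test(
                sites, structure, ann,
                statistic=cl.get("statistic", "max_blade_count"),
                n_permutations=int(cl.get("n_permutations", 10_000)),
                seed=config.seed,
            )
            cluster_path = out / "clustering.json"
            payload = {
                "provenance": {"tool": f"parablade {__version__}",
                               "config_sha256": config.config_hash(),
                               "seed": config.seed},
                "statistic": result.statistic,
                "observed": result.observed,
                "p_value": result.p_value,
                "n_permutations": result.n_permutations,
                "exhaustive": result.exhaustive,
            }
            cluster_path.write_text(json.dumps(payload, indent=2) + "\n")
            artifacts["clustering"] = str(cluster_path)
            log.info("clustering %s observed=%.3f p=%.4g",
                     result.statistic, result.observed, result.p_value)
        complete = True
    finally:
        manifest = out / "MANIFEST.tsv"
        with open(manifest, "w") as fh:
            fh.write(prefix)
            fh.write("artifact\tpath\tstatus\n")
            status = "complete" if complete else "INCOMPLETE"
            for name, path in artifacts.items():
                fh.write(f"{name}\t{Path(path).name}\t{status}\n")
        artifacts["manifest"] = str(manifest)
    return artifacts
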