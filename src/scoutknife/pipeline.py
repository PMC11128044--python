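"""End-to-end orchestration: genes -> occupancy -> plan -> replicates ->
trees -> consensus -> congruence metrics, with provenance artifacts.

One call (or ``scoutknife run``) takes a gene directory (or a concatenated
FASTA plus partition file), draws the seeded replicate manifest, obtains
one tree per replicate — from the built-in JC+NJ backend, from supplied
true gene trees, or by emitting external inference commands — and builds
consensus trees at the requested thresholds. All randomness flows from the
single seed; rerunning an identical config reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import occupancy as occ
from . import quartets, sampling, seqio, trees
from .infer import jc_distance_matrix, neighbor_joining

__all__ = ["RunConfig", "RunResult", "run_end_to_end", "load_config"]

logger = logging.getLogger("scoutknife")

BACKENDS = ("builtin", "external-commands", "gene-trees")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one run.

    ``sample_size`` may be an integer or ``"auto"``: auto picks the
    smallest n giving every replicate a 99.9% chance of containing the
    minimum-occupancy taxon. ``gene_trees`` (a Newick treelist path,
    aligned to gene ids by order) enables the "gene-trees" backend, where
    the treelist is the pool of sampled genes' true trees instead of
    per-replicate inference. ``command_template`` drives the
    external-commands backend.
    """

    genes_dir: str | None = None
    alignment: str | None = None
    partitions: str | None = None
    out_dir: str = "scoutknife_out"
    sample_size: int | str = 100
    replicates: int = 100
    seed: int = 0
    consensus_thresholds: tuple[float, ...] = (0.5, 0.7)
    backend: str = "builtin"
    reference_tree: str | None = None
    gene_trees: str | None = None
    command_template: str = "iqtree -s {aln} -spp {part} -pre {prefix}"
    auto_target: float = 0.999

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend {self.backend!r} not one of {BACKENDS}")
        for t in self.consensus_thresholds:
            if not 0 < t <= 1:
                raise ValueError(f"threshold {t} outside (0, 1]")
        if self.sample_size != "auto" and int(self.sample_size) < 1:
            raise ValueError("sample_size must be >= 1 or 'auto'")
        if self.genes_dir is None and self.alignment is None:
            raise ValueError("need genes_dir or alignment+partitions")
        if self.alignment is not None and self.partitions is None:
            raise ValueError("alignment input requires a partition file")


@dataclass
class RunResult:
    config: RunConfig
    profile: occ.OccupancyProfile
    sample_size: int
    manifest: sampling.ReplicateManifest
    treelist: list[trees.Tree] = field(default_factory=list)
    consensus: dict[float, trees.Tree] = field(default_factory=dict)
    metrics: dict[float, dict[str, float]] = field(default_factory=dict)
    command_lines: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a TOML run config; keyword overrides win over file values."""
    data = tomllib.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "consensus_thresholds" in data:
        data["consensus_thresholds"] = tuple(data["consensus_thresholds"])
    return RunConfig(**data)


def _load_genes(config: RunConfig) -> list[seqio.GeneAlignment]:
    if config.genes_dir is not None:
        return seqio.read_gene_fastas(config.genes_dir)
    matrix = seqio.read_fasta_alignment(config.alignment, gene_id="supermatrix")
    parts = seqio.read_partition_file(config.partitions)
    return seqio.split_supermatrix(
        seqio.SuperMatrix(seqs=dict(matrix.seqs), partitions=parts)
    )


def _echo_config(config: RunConfig, sample_size: int, out: Path) -> None:
    resolved = {k: v for k, v in vars(config).items()}
    resolved["resolved_sample_size"] = sample_size
    with (out / "config_echo.json").open("w") as fh:
        json.dump(resolved, fh, indent=2, default=str)
        fh.write("\n")


def run_end_to_end(config: RunConfig) -> RunResult:
    """Run the full subsample-infer-consense pipeline and write artifacts.

    Writes to ``config.out_dir``: manifest.tsv, treelist.nwk, one
    consensus_t<thr>.nwk per threshold, occupancy.tsv, metrics.tsv (when a
    reference tree is given), commands.txt (external backend), a resolved
    config echo, and run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        genes = _load_genes(config)
        logger.info("loaded %d genes", len(genes))
        profile = occ.occupancy_profile(genes)

        # resolve sample size (the 'auto' design rule)
        min_taxon, k_min = profile.min_taxon()
        if config.sample_size == "auto":
            n = occ.auto_sample_size(profile.N, max(k_min, 1), config.auto_target)
            logger.info(
                "auto sample size: n=%d targets %.1f%% representation of %s (K=%d)",
                n, 100 * config.auto_target, min_taxon, k_min,
            )
        else:
            n = int(config.sample_size)
        if n > profile.N:
            raise ValueError(
                f"sample size n={n} exceeds the {profile.N} available genes; "
                "use a smaller --sample-size or 'auto'"
            )

        result = RunResult(
            config=config,
            profile=profile,
            sample_size=n,
            manifest=sampling.draw_plan(
                sampling.SamplingPlan(N=profile.N, n=n, R=config.replicates, seed=config.seed),
                [g.gene_id for g in genes],
            ),
        )

        # warn about taxa likely to vanish from replicates
        for taxon, k in sorted(profile.K.items()):
            if k == 0:
                result.warnings.append(f"taxon {taxon} has no data in any gene")
                continue
            spec = occ.HypergeomSpec(N=profile.N, K=k, n=n)
            p_absent = 1.0 - occ.prob_at_least(spec, 1)
            if p_absent > 0.01:
                msg = (
                    f"taxon {taxon} occupies {k}/{profile.N} genes; "
                    f"P(absent from a replicate) = {100 * p_absent:.2f}%"
                )
                result.warnings.append(msg)
                logger.warning(msg)

        _write_occupancy(profile, out / "occupancy.tsv")
        sampling.write_manifest(result.manifest, out / "manifest.tsv")

        if config.backend == "builtin":
            matrices = sampling.materialize_replicates(result.manifest, genes)
            for i, m in enumerate(matrices, 1):
                tree = neighbor_joining(jc_distance_matrix(m))
                result.treelist.append(tree)
                if i % 25 == 0:
                    logger.info("inferred %d/%d replicate trees", i, len(matrices))
        elif config.backend == "gene-trees":
            if config.gene_trees is None:
                raise ValueError("backend 'gene-trees' requires a gene_trees treelist")
            gtrees = trees.read_treelist(config.gene_trees)
            if len(gtrees) != profile.N:
                raise ValueError(
                    f"gene_trees has {len(gtrees)} trees for {profile.N} genes"
                )
            by_id = {g.gene_id: t for g, t in zip(genes, gtrees)}
            for _rep, gene_ids in result.manifest.rows:
                result.treelist.extend(by_id[g] for g in gene_ids)
        else:  # external-commands
            paths = {}
            for rep_id, _ in result.manifest.rows:
                rep_dir = out / f"rep_{rep_id:03d}"
                rep_dir.mkdir(exist_ok=True)
                paths[rep_id] = {
                    "aln": str(rep_dir / "alignment.fasta"),
                    "part": str(rep_dir / "partitions.txt"),
                    "prefix": str(rep_dir / "infer"),
                }
            matrices = sampling.materialize_replicates(result.manifest, genes)
            for (rep_id, _), m in zip(result.manifest.rows, matrices):
                seqio.write_fasta(m, paths[rep_id]["aln"])
                seqio.write_partition_file(m.partitions, paths[rep_id]["part"])
            result.command_lines = sampling.external_command_lines(
                result.manifest, config.command_template, paths
            )
            (out / "commands.txt").write_text("\n".join(result.command_lines) + "\n")
            logger.info("emitted %d inference commands", len(result.command_lines))

        if result.treelist:
            trees.write_treelist(result.treelist, out / "treelist.nwk")
            for thr in config.consensus_thresholds:
                cons = trees.consensus_tree(result.treelist, thr)
                result.consensus[thr] = cons
                (out / f"consensus_t{thr:.2f}.nwk").write_text(
                    trees.write_newick(cons) + "\n"
                )
            if config.reference_tree is not None:
                ref = trees.parse_newick(Path(config.reference_tree).read_text())
                for thr, cons in result.consensus.items():
                    status = quartets.quartet_status(cons, ref)
                    m = quartets.similarity_metrics(status)
                    m.update(
                        Q=status.Q, s=status.s, d=status.d,
                        r1=status.r1, r2=status.r2, u=status.u,
                    )
                    result.metrics[thr] = m
                _write_metrics(result.metrics, out / "metrics.tsv")

        _echo_config(config, n, out)
        logger.info("done in %.1fs", time.time() - t0)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_occupancy(profile: occ.OccupancyProfile, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("taxon\tgenes_present\tfraction\n")
        for taxon in sorted(profile.K):
            k = profile.K[taxon]
            fh.write(f"{taxon}\t{k}\t{k / profile.N:.4f}\n")


def _write_metrics(metrics: dict[float, dict[str, float]], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("threshold\tmetric\tvalue\n")
        for thr in sorted(metrics):
            for name, value in metrics[thr].items():
                fh.write(f"{thr:.2f}\t{name}\t{value:.6g}\n")


def output_digest(out_dir: str | Path) -> str:
    """SHA-256 over the scientific artifacts, for determinism checks.

    The log and the config echo are excluded: they record provenance
    (timestamps, output paths), not results.
    """
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("run.log", "config_echo.json"):
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()
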