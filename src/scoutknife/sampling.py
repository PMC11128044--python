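"""Seeded replicate sampling: n genes per replicate, drawn uniformly
without replacement within a replicate, independently across replicates.

The defining rule of the design (and the difference from a site
bootstrap): a gene can never appear twice in the same replicate, but may
recur across replicates. Each replicate draws from its own RNG substream
derived from (seed, replicate_id), so extending a run with more replicates
never changes the earlier ones, and a manifest is fully reproducible from
the plan alone.
"""

from __future__ import annotations

import shlex
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import GeneAlignment, SuperMatrix, concatenate

__all__ = [
    "SamplingPlan",
    "ReplicateManifest",
    "draw_plan",
    "materialize_replicates",
    "external_command_lines",
    "write_manifest",
    "read_manifest",
]


@dataclass(frozen=True)
class SamplingPlan:
    """How to subsample: N source genes, n per replicate, R replicates."""

    N: int
    n: int = 100
    R: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n <= self.N:
            raise ValueError(
                f"sample size n={self.n} outside [1, N={self.N}]; "
                "use a smaller n or 'auto'"
            )
        if self.R < 1:
            raise ValueError(f"replicate count R={self.R} must be >= 1")


@dataclass(frozen=True)
class ReplicateManifest:
    """Which genes each replicate drew; replicate ids run 1..R."""

    rows: tuple[tuple[int, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        for rep_id, gene_ids in self.rows:
            if len(set(gene_ids)) != len(gene_ids):
                raise ValueError(f"replicate {rep_id}: repeated gene id")


def _replicate_rng(seed: int, replicate_id: int) -> np.random.Generator:
    # substream keyed on (seed, replicate_id): stable under adding replicates
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, replicate_id))))


def draw_plan(plan: SamplingPlan, gene_ids: list[str]) -> ReplicateManifest:
    """Draw the full manifest for a plan.

    Each replicate is a uniform sample of n distinct genes via a partial
    Fisher-Yates shuffle; within-replicate order is the draw order.
    Identical (plan, gene_ids) always reproduce the identical manifest.
    """
    if len(gene_ids) != plan.N:
        raise ValueError(f"plan expects N={plan.N} genes, got {len(gene_ids)}")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene ids are not unique")
    rows = []
    for rep_id in range(1, plan.R + 1):
        rng = _replicate_rng(plan.seed, rep_id)
        idx = list(range(plan.N))
        for j in range(plan.n):
            k = j + int(rng.integers(plan.N - j))
            idx[j], idx[k] = idx[k], idx[j]
        rows.append((rep_id, tuple(gene_ids[i] for i in idx[: plan.n])))
    return ReplicateManifest(rows=tuple(rows))


def materialize_replicates(
    manifest: ReplicateManifest, genes: list[GeneAlignment]
) -> list[SuperMatrix]:
    """Concatenate each replicate's sampled genes into a supermatrix.

    A taxon absent from every sampled gene of a replicate is absent from
    that replicate's matrix entirely.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for rep_id, gene_ids in manifest.rows:
        try:
            sampled = [by_id[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"replicate {rep_id}: unknown gene id {exc.args[0]!r}") from None
        out.append(concatenate(sampled))
    return out


def external_command_lines(
    manifest: ReplicateManifest,
    template: str,
    paths: dict[int, dict[str, str]],
) -> list[str]:
    """Substitute per-replicate paths into a shell command template.

    *template* uses ``{aln}``/``{part}``-style placeholders; *paths* maps
    replicate id to placeholder values. Paths are shell-quoted. Commands
    are emitted, never executed.
    """
    import string

    fields = [f for _, f, _, _ in string.Formatter().parse(template) if f]
    if not fields:
        warnings.warn("command template contains no placeholders; emitting identical lines")
    lines = []
    for rep_id, _ in manifest.rows:
        values = paths.get(rep_id, {})
        missing = [f for f in fields if f not in values]
        if missing:
            raise KeyError(
                f"replicate {rep_id}: no value for placeholder(s) {', '.join(missing)}"
            )
        quoted = {k: shlex.quote(str(v)) for k, v in values.items()}
        lines.append(template.format(**quoted))
    return lines


def write_manifest(manifest: ReplicateManifest, path: str | Path) -> None:
    """TSV: replicate id, then the sampled gene ids in draw order."""
    with Path(path).open("w") as fh:
        fh.write("replicate\tgene_ids\n")
        for rep_id, gene_ids in manifest.rows:
            fh.write(f"{rep_id}\t{','.join(gene_ids)}\n")


def read_manifest(path: str | Path) -> ReplicateManifest:
    rows = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        rep, ids = line.split("\t")
        rows.append((int(rep), tuple(ids.split(","))))
    return ReplicateManifest(rows=tuple(rows))
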