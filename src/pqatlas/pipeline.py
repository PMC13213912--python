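"""End-to-end orchestration: shuffle → MQN → PQ → PQk-Means → nested atlas.

The workflow runs in four computational stages, each persisting its artifacts
to the output directory so stages are independently re-runnable and the run
is resumable at stage boundaries:

1. input shuffling and sharding (removes ordering effects from sorted input);
2. SMILES parsing and MQN computation, streamed per shard;
3. PQ codebook training and encoding of all MQN vectors into 6-byte codes;
4. PQk-Means clustering, streaming assignment, representative selection, and
   the nested tree-map atlas over representatives and cluster members.

A :class:`RunManifest` records per-stage counts, seeds and artifact hashes;
valid-molecule counts must reconcile across stages (molecules in = codes out
= labels out).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .descriptors import (
    MoleculeRecord,
    ecfp_matrix,
    mqn_matrix,
    panel_frame,
    read_smiles,
)
from .pq import ProductQuantizer, load_codes, save_codes
from .pqkmeans import PQKMeans, compact, select_representatives
from .treemap import (
    NestedAtlas,
    assemble_atlas,
    build_primary,
    build_secondary,
    save_atlas,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "shuffle_input", "run"]


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run.

    Defaults mirror the reference settings: m=6 subspaces, L=256 codewords,
    20 codebook iterations. ``n_clusters`` is fully configurable (100,000 is
    the documented at-scale value; desk-scale runs use far fewer). Sample
    sizes of ``None`` mean "use everything", which also makes training
    invariant to input order.
    """

    input_paths: list[str]
    output_dir: str
    n_clusters: int
    shard_size: int = 100_000
    shuffle_seed: int = 0
    m: int = 6
    L: int = 256
    codebook_iters: int = 20
    codebook_sample: int | None = None
    codebook_seed: int = 0
    fit_sample: int | None = None
    fit_iters: int = 20
    fit_seed: int = 0
    batch_size: int = 100_000
    knn_k: int = 10
    layout_seed: int = 0
    ecfp_bits: int = 2048
    knn_mode: str = "exact"

    def __post_init__(self):
        for name in ("n_clusters", "shard_size", "m", "L", "codebook_iters", "fit_iters", "batch_size", "knn_k", "ecfp_bits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"version": self.version, "config": self.config, "stages": self.stages}, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def shuffle_input(
    files: list[str | Path], seed: int, out_dir: str | Path, shard_size: int = 100_000
) -> list[Path]:
    """Seeded permutation of all input lines, re-sharded.

    Preserves the multiset of lines exactly; same seed gives the identical
    permutation.
    """
    lines: list[str] = []
    for f in files:
        path = Path(f)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text() if path.suffix != ".gz" else __import__("gzip").open(path, "rt").read()
        lines.extend(l for l in text.splitlines() if l.strip())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(lines))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    shards: list[Path] = []
    for s, start in enumerate(range(0, len(lines), shard_size)):
        shard = out / f"shard_{s:04d}.smi"
        shard.write_text("\n".join(lines[i] for i in order[start : start + shard_size]) + "\n")
        shards.append(shard)
    return shards


def _stage_parse(shards: list[Path]) -> tuple[list[MoleculeRecord], int]:
    records: list[MoleculeRecord] = []
    skipped = 0
    idx = 0
    for shard in shards:
        shard_skipped = 0
        for rec in read_smiles(shard, start_id=idx):
            if not rec.valid:
                shard_skipped += 1
            records.append(rec)
            idx += 1
        logger.info("parsed %s: %d records, %d skipped", shard.name, idx, shard_skipped)
        skipped += shard_skipped
    return records, skipped


def run(config: PipelineConfig) -> tuple[NestedAtlas, RunManifest]:
    """Execute all stages in order; returns the atlas and the run manifest.

    Any stage failure halts the run with the manifest (written to
    ``run_manifest.json``) recording the stages completed so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    manifest_path = out / "run_manifest.json"
    try:
        atlas = _run_stages(config, out, manifest)
    finally:
        manifest.save(manifest_path)
    return atlas, manifest


def _seeded_subsample(n: int, size: int | None, seed: int) -> np.ndarray | None:
    if size is None or size >= n:
        return None
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=size, replace=False)


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> NestedAtlas:
    # stage 1: shuffle + shard
    shards = shuffle_input(
        config.input_paths, config.shuffle_seed, out / "shards", config.shard_size
    )
    manifest.record(
        "shuffle",
        n_shards=len(shards),
        seed=config.shuffle_seed,
        hashes=[_sha256(s) for s in shards],
    )

    # stage 2: parse + MQN
    records, skipped = _stage_parse(shards)
    valid = [r for r in records if r.valid]
    n_valid = len(valid)
    if n_valid == 0:
        raise ValueError("no valid molecules in input")
    if config.n_clusters > n_valid:
        raise ValueError(
            f"n_clusters={config.n_clusters} exceeds the {n_valid} valid molecules; "
            "lower n_clusters before running the heavy stages"
        )
    ids, X = mqn_matrix(valid)
    mol_table = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "name": [r.name for r in records],
            "valid": [r.valid for r in records],
        }
    )
    mol_table.to_csv(out / "molecules.csv", index=False)
    np.save(out / "mqn.npy", X)
    manifest.record(
        "mqn",
        n_input=len(records),
        n_valid=n_valid,
        n_skipped=skipped,
        hashes=[_sha256(out / "mqn.npy")],
    )

    # stage 3: PQ codebook + encoding
    sub = _seeded_subsample(n_valid, config.codebook_sample, config.codebook_seed)
    train_X = X if sub is None else X[sub]
    pq = ProductQuantizer(
        n_subspaces=config.m,
        n_codewords=config.L,
        n_iter=config.codebook_iters,
        batch_size=config.batch_size,
        random_state=config.codebook_seed,
    ).fit(train_X)
    pq.save(out / "codebook.npz")
    codes = pq.transform(X)
    save_codes(codes, out / "codes.bin", pq)
    manifest.record(
        "pq",
        n_codes=int(codes.shape[0]),
        code_bytes=int(codes.shape[1]),
        seed=config.codebook_seed,
        hashes=[_sha256(out / "codes.bin")],
    )

    # stage 4a: clustering + representatives
    sub = _seeded_subsample(n_valid, config.fit_sample, config.fit_seed)
    train_codes = codes if sub is None else codes[sub]
    model = PQKMeans(
        n_clusters=config.n_clusters,
        tables=pq.sd_tables_,
        max_iter=config.fit_iters,
        batch_size=config.batch_size,
        random_state=config.fit_seed,
    ).fit(train_codes)
    assignment = model.predict(codes)
    model, assignment, mapping = compact(model, assignment)
    assign_table = pd.DataFrame(
        {"molecule_id": ids, "cluster_id": assignment.labels, "sd": assignment.distances}
    )
    assign_table.to_csv(out / "assignment.csv", index=False)
    reps = select_representatives(codes, assignment, model, pq.sd_tables_, ids=ids)
    reps.to_csv(out / "representatives.csv")
    manifest.record(
        "cluster",
        n_requested=config.n_clusters,
        n_populated=int(model.n_clusters),
        n_assigned=int(len(assignment.labels)),
        seed=config.fit_seed,
        hashes=[_sha256(out / "assignment.csv")],
    )

    # stage 4b: nested atlas
    by_id = {r.id: r for r in valid}
    id_to_row = {int(mid): row for row, mid in enumerate(ids)}
    rep_records = [by_id[int(m)] for m in reps["molecule_id"]]
    rep_rows = [id_to_row[int(m)] for m in reps["molecule_id"]]
    rep_meta = panel_frame(rep_records).reset_index().rename(columns={"id": "molecule_id"})
    rep_meta.insert(0, "cluster_id", reps.index.to_numpy())
    rep_meta.insert(2, "smiles", [r.smiles for r in rep_records])
    primary = build_primary(
        X[rep_rows], rep_meta, k=config.knn_k, seed=config.layout_seed, mode=config.knn_mode
    )
    secondaries = {}
    for cid in reps.index:
        member_rows = np.flatnonzero(assignment.labels == cid)
        member_records = [by_id[int(ids[r])] for r in member_rows]
        _, fps = ecfp_matrix(member_records, n_bits=config.ecfp_bits)
        meta = pd.DataFrame(
            {
                "molecule_id": [r.id for r in member_records],
                "smiles": [r.smiles for r in member_records],
            }
        )
        secondaries[int(cid)] = build_secondary(
            fps,
            meta,
            cluster_id=int(cid),
            k=config.knn_k,
            seed=config.layout_seed,
            mode=config.knn_mode,
        )
    atlas = assemble_atlas(primary, secondaries, dataset_size=n_valid)
    atlas_dir = save_atlas(atlas, out / "atlas")
    manifest.record(
        "atlas",
        n_primary_nodes=primary.tree.n,
        n_secondary_maps=len(secondaries),
        n_molecules=atlas.manifest["n_molecules"],
        hashes=[_sha256(atlas_dir / "manifest.json")],
    )
    return atlas
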