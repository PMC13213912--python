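"""Synthetic inputs: drug-like SMILES libraries and labelled MQN-shaped blobs.

Two generators make every pipeline stage testable without any download:

* :func:`generate_smiles_library` enumerates scaffold × substituent fragment
  combinations into valid, parseable, drug-like SMILES (MW ≤ 500), emulating
  a make-on-demand combinatorial library. Chemistry realism is not the
  contract — validity, determinism and structural diversity (several ring
  counts, varying polarity) are.
* :func:`generate_mqn_blobs` produces labelled clusters of 42-dimensional
  non-negative integer count vectors with controllable separation-to-spread
  ratio, for clustering-recovery tests where ground truth is known.

Both are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .descriptors import MQN_DIM

__all__ = ["BlobSpec", "generate_mqn_blobs", "generate_smiles_library"]

# Scaffold templates with one or two substitution sites ({R1}, {R2}).
# Ring counts span 0-4 so MQN space is non-degenerate across the library.
_SCAFFOLDS = [
    "CC({R1})CC{R2}",                      # 0 rings, aliphatic
    "{R1}CCOCC{R2}",                       # 0 rings, ether chain
    "{R1}CC(=O)N{R2}",                     # 0 rings, amide
    "c1ccc({R1})cc1{R2}",                  # 1 ring, benzene
    "c1ccnc({R1})c1{R2}",                  # 1 ring, pyridine
    "C1CCN(C1)C(=O){R1}",                  # 1 ring, pyrrolidine amide
    "c1cc({R1})oc1{R2}",                   # 1 ring, furan
    "C1CCC(CC1)N{R1}",                     # 1 ring, cyclohexylamine
    "c1ccc2[nH]c({R1})cc2c1",              # 2 rings, indole
    "c1ccc(-c2ccc({R1})cc2)cc1",           # 2 rings, biphenyl
    "c1ccc2ncccc2c1{R1}",                  # 2 rings, quinoline
    "C1CN(CCN1{R1})c1ccccc1",              # 2 rings, phenylpiperazine
    "c1ccc(CN2CCC(CC2){R1})cc1",           # 2 rings, benzylpiperidine
    "c1ccc(-c2nc3ccccc3[nH]2)cc1{R1}",     # 3 rings, phenylbenzimidazole
    "C1CCC2(CC1)CCN(CC2)C(=O){R1}",        # 2 rings spiro
    "c1ccc2c(c1)oc1ccccc12",               # 3 rings, dibenzofuran (no site)
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",      # 3 rings, terphenyl (no site)
    "C1CC2CCC1CC2{R1}",                    # 2 fused aliphatic rings
    "c1cnc2c(c1)ccc1cccnc12",              # 3 rings, phenanthroline core
    "c1ccc(-n2cnc3ccccc32)cc1{R1}",        # 3 rings, N-arylbenzimidazole
    "C1CCC(CC1)C1CCC(CC1)C1CC1{R1}",       # 3 aliphatic rings
    "c1ccc2c(c1)Cc1ccccc1-2",              # 3 rings, fluorene (no site)
    "c1ccc(-c2ccc3c(c2)oc2ccccc23)cc1",    # 4 rings
]

_SUBSTITUENTS = [
    "",  # bare hydrogen at the site
    "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(=O)OC", "C(=O)NC",
    "S(=O)(=O)N", "S(=O)(=O)C", "C(F)(F)F", "CO", "CN", "CCO", "CCN",
    "OC(F)F", "[N+](=O)[O-]",
]


def _fill(template: str, r1: str, r2: str) -> str:
    smi = template.replace("{R1}", r1 if "{R1}" in template else "")
    smi = smi.replace("{R2}", r2)
    return smi


def generate_smiles_library(
    n: int, seed: int, path: str | Path | None = None, max_mw: float = 500.0
) -> list[str]:
    """Enumerate ``n`` valid drug-like SMILES from fragment combinations.

    Candidates are drawn as seeded (scaffold, substituent, substituent)
    picks, validated with RDKit, and filtered to MW ≤ ``max_mw``. Duplicates
    are allowed, mirroring combinatorial enumeration. If ``path`` is given,
    the library is also written one SMILES per line.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        tpl = _SCAFFOLDS[int(rng.integers(len(_SCAFFOLDS)))]
        r1 = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        r2 = _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
        smi = _fill(tpl, r1, r2)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or Descriptors.MolWt(mol) > max_mw:
            continue
        out.append(Chem.MolToSmiles(mol))
    if path is not None:
        Path(path).write_text("\n".join(out) + "\n")
    return out


@dataclass(frozen=True)
class BlobSpec:
    """Design of a labelled count-vector blob fixture.

    ``separation`` is the minimum pairwise Euclidean distance enforced
    between cluster centers, expressed as a multiple of the expected
    within-cluster deviation norm (≈ ``spread · sqrt(dim)``). ``spread`` is
    the per-coordinate noise scale; noise is rounded to integers and
    truncated at zero so every generated vector stays a valid count vector.
    """

    n: int
    k: int
    spread: float = 1.0
    separation: float = 5.0
    center_low: int = 0
    center_high: int = 30
    dim: int = MQN_DIM
    seed: int = 0


def _draw_centers(spec: BlobSpec, rng: np.random.Generator) -> np.ndarray:
    min_dist = spec.separation * spec.spread * np.sqrt(spec.dim)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.k:
        cand = rng.integers(spec.center_low, spec.center_high + 1, size=spec.dim)
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
        attempts += 1
        if attempts > 10_000 * spec.k:
            raise ValueError(
                "could not place cluster centers at the requested separation; "
                "widen the center range or lower the separation"
            )
    return np.asarray(centers, dtype=np.int64)


def generate_mqn_blobs(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labelled MQN-shaped blobs.

    Returns ``(X, labels, centers)``: ``X`` is ``(n, dim)`` of non-negative
    integers, ``labels`` the ground-truth cluster per row, ``centers`` the
    ``(k, dim)`` integer centers. Cluster sizes are as equal as ``n`` and
    ``k`` permit.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _draw_centers(spec, rng)
    base, extra = divmod(spec.n, spec.k)
    sizes = np.full(spec.k, base, dtype=np.int64)
    sizes[:extra] += 1
    labels = np.repeat(np.arange(spec.k), sizes)
    noise = np.rint(rng.normal(0.0, spec.spread, size=(spec.n, spec.dim))).astype(np.int64)
    X = np.maximum(centers[labels] + noise, 0)
    return X, labels, centers
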