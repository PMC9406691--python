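"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`generate` — a congeneric series: one scaffold (by default the
  fluorinated imidazo[1,2-a]pyridine acetamide template), enumerable
  aliphatic substituents grafted at the phenyl ortho/meta/para sites, and
  activity = baseline + additive per-fragment effects + Gaussian noise.
  The planted effect map is returned with the data so recovery tests never
  depend on hidden state.
* :func:`fixture_molecules` — the ten reference molecules (template A and
  analogues A1–A9) with their reference predicted activities.
* :func:`synthetic_descriptor_matrix` — a descriptor table with a known
  linear signal plus engineered near-constant and near-duplicate decoy
  columns that exercise the descriptor filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem

from .design import _phenyl_sites
from .records import MoleculeRecord
from .smiles_attributes import SmilesError, canonize_smiles

#: template molecule A: the design scaffold used throughout
TEMPLATE_A = "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1ccccc1"

#: reference molecules with reference predicted pKi
FIXTURES: tuple[tuple[str, str, float], ...] = (
    ("A",  "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1ccccc1", 6.7559),
    ("A1", "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1ccccc1C", 7.4613),
    ("A2", "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1cccc(c1)C", 7.1357),
    ("A3", "Cc1ccc(cc1)c1nc2n(c1CC(=O)N(C)C)cc(cc2)F", 7.5160),
    ("A4", "CCc1ccccc1c1nc2n(c1CC(=O)N(C)C)cc(cc2)F", 7.1291),
    ("A5", "CCc1cccc(c1)c1nc2n(c1CC(=O)N(C)C)cc(cc2)F", 7.3736),
    ("A6", "CCc1ccc(cc1)c1nc2n(c1CC(=O)N(C)C)cc(cc2)F", 7.3465),
    ("A7", "CCN(C(=O)Cc1c(nc2n1cc(F)cc2)c1ccccc1C(C)C)C", 8.0238),
    ("A8", "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1cccc(c1)C(C)C", 7.7217),
    ("A9", "Fc1ccc2n(c1)c(CC(=O)N(C)C)c(n2)c1ccc(cc1)C(C)C", 7.6353),
)


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic congeneric series.

    Effects are additive activity increments in pKi units per present
    fragment, position-independent; noise is Gaussian on the log scale.
    """

    scaffold: str = TEMPLATE_A
    effects: dict = field(default_factory=lambda: {
        "C": 0.5,       # methyl
        "CC": -0.3,     # ethyl
        "C(C)C": 0.8,   # isopropyl
    })
    positions: tuple[str, ...] = ("ortho", "meta", "para")
    baseline: float = 6.7
    noise_sigma: float = 0.05
    n: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n < 4:
            raise ValueError("need n >= 4")


def decorate(scaffold: str, assignment: dict[str, str | None]) -> str:
    """Graft substituents onto the scaffold phenyl at the assigned sites.

    ``assignment`` maps position name -> substituent SMILES (or None for an
    unmodified site).  All grafts happen in one graph edit so multiply
    substituted analogues are reachable.
    """
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise SmilesError(f"cannot parse scaffold: {scaffold!r}")
    sites = _phenyl_sites(mol)
    combo = Chem.RWMol(mol)
    for pos, frag_smiles in assignment.items():
        if frag_smiles is None:
            continue
        frag = Chem.MolFromSmiles(frag_smiles)
        if frag is None:
            raise SmilesError(f"cannot parse substituent: {frag_smiles!r}")
        offset = combo.GetNumAtoms()
        combo = Chem.RWMol(Chem.CombineMols(combo, frag))
        combo.AddBond(sites[pos], offset, Chem.BondType.SINGLE)
    Chem.SanitizeMol(combo)
    return canonize_smiles(Chem.MolToSmiles(combo))


def generate(config: GeneratorConfig) -> tuple[list[MoleculeRecord], dict]:
    """Sample a congeneric series with planted additive fragment effects.

    Distinct substitution patterns are sampled without replacement; the
    returned ground truth carries the effect map, baseline, noise level and
    the per-molecule substitution patterns.
    """
    fragments = list(config.effects)
    options: list[str | None] = [None] + fragments
    patterns = list(product(options, repeat=len(config.positions)))
    if config.n > len(patterns):
        raise ValueError(
            f"n={config.n} exceeds the {len(patterns)} distinct patterns"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(patterns), size=config.n, replace=False)

    records, assignments = [], {}
    for i, idx in enumerate(chosen):
        pattern = patterns[idx]
        assignment = dict(zip(config.positions, pattern))
        smiles = decorate(config.scaffold, assignment)
        effect_sum = sum(config.effects[f] for f in pattern if f is not None)
        activity = (
            config.baseline + effect_sum
            + rng.normal(0.0, config.noise_sigma)
        )
        mol_id = f"M{i + 1:03d}"
        records.append(MoleculeRecord(mol_id, smiles, float(activity)))
        assignments[mol_id] = {
            p: f for p, f in assignment.items() if f is not None
        }
    ground_truth = {
        "scaffold": config.scaffold,
        "baseline": config.baseline,
        "effects": dict(config.effects),
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "assignments": assignments,
    }
    return records, ground_truth


def fixture_molecules() -> list[MoleculeRecord]:
    """The ten reference molecules (A, A1–A9) with reference activities."""
    return [
        MoleculeRecord(mol_id, smiles, pki)
        for mol_id, smiles, pki in FIXTURES
    ]


def synthetic_descriptor_matrix(
    n_molecules: int = 33,
    n_descriptors: int = 12,
    k_informative: int = 2,
    seed: int = 0,
    noise_sigma: float = 0.0,
    baseline: float = 6.5,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Descriptor table with planted linear signal and filter-bait decoys.

    The first ``k_informative`` columns combine linearly (known
    coefficients) into the response; among the decoys one column is
    engineered 96%-constant and one is a sample-correlation-0.97 duplicate
    of the first informative column.
    """
    if k_informative > n_descriptors:
        raise ValueError("k_informative exceeds n_descriptors")
    if n_descriptors < k_informative + 2:
        raise ValueError("need at least two decoy columns")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_molecules, n_descriptors))
    names = [f"D{j:03d}" for j in range(n_descriptors)]

    coefs = rng.uniform(0.5, 2.0, size=k_informative)
    coefs *= rng.choice([-1.0, 1.0], size=k_informative)
    y = baseline + X[:, :k_informative] @ coefs
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=n_molecules)

    # decoy 1: 96%-constant column
    const_col = n_descriptors - 2
    col = np.full(n_molecules, 1.0)
    n_varied = max(1, int(np.floor(0.04 * n_molecules)))
    varied = rng.choice(n_molecules, size=n_varied, replace=False)
    col[varied] = rng.normal(5.0, 1.0, size=n_varied)
    X[:, const_col] = col

    # decoy 2: exact sample-correlation-0.97 duplicate of column 0.  Its
    # noise part is orthogonalized against every informative column so the
    # duplicate is always the weaker-to-response member of the pair.
    dup_col = n_descriptors - 1
    x0 = X[:, 0]
    x0s = (x0 - x0.mean()) / x0.std()
    e = rng.normal(size=n_molecules)
    e = e - e.mean()
    Z = X[:, :k_informative] - X[:, :k_informative].mean(axis=0)
    coef, *_ = np.linalg.lstsq(Z, e, rcond=None)
    e = e - Z @ coef  # residual: orthogonal to the span of the signal columns
    e = e / e.std()
    rho = 0.97
    X[:, dup_col] = rho * x0s + np.sqrt(1.0 - rho**2) * e

    matrix = pd.DataFrame(
        X, index=[f"M{i + 1:03d}" for i in range(n_molecules)], columns=names
    )
    ground_truth = {
        "informative": names[:k_informative],
        "coefficients": dict(zip(names[:k_informative], map(float, coefs))),
        "baseline": baseline,
        "noise_sigma": noise_sigma,
        "constant_decoy": names[const_col],
        "duplicate_pair": [names[0], names[dup_col]],
        "seed": seed,
    }
    return matrix, y, ground_truth
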