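"""Monte Carlo optimization of correlation weights over attribute keys.

The model assigns every sufficiently common attribute key a real-valued
correlation weight CW.  A molecule's descriptor is the sum of weights over
its attribute occurrences,

    DCW(T, N_epoch) = Σ CW(S_k) + Σ CW(SS_k) + Σ CW(SSS_k)
                    + Σ CW(ATOMPAIR) + Σ CW(NOSP) + Σ CW(BOND) + Σ CW(HALO)
                    + Σ CW(PT2_k) + Σ CW(PT3_k) + Σ CW(VS2_k) + Σ CW(VS3_k)
                    + Σ CW(NNC_k),

and the activity model is the calibration line pKi = C0 + C1 · DCW fitted by
ordinary least squares on the training set.  T is the rarity threshold: keys
present in fewer than T training molecules are blocked (weight pinned at 0).
N_epoch Monte Carlo epochs of greedy coordinate perturbation maximize the
training target (r² by default, optionally blended with IIC).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .graph_invariants import full_attribute_profile
from .records import AttributeKey, AttributeProfile, MoleculeRecord
from .validation import iic as _iic_metric


@lru_cache(maxsize=4096)
def profile_for(smiles: str) -> AttributeProfile:
    """Cached full attribute profile (SMILES + graph attributes)."""
    return full_attribute_profile(smiles, smiles)


@dataclass
class SplitDataset:
    """Disjoint training/test sets of molecules with observed activities."""

    training: list[MoleculeRecord]
    test: list[MoleculeRecord]
    balance: dict = field(default_factory=dict)

    def with_training_activities(self, activities) -> "SplitDataset":
        new_train = [
            MoleculeRecord(r.molecule_id, r.smiles, float(a), r.split)
            for r, a in zip(self.training, activities)
        ]
        return SplitDataset(new_train, list(self.test), dict(self.balance))


@dataclass
class CWModel:
    """A trained (or initialized) correlation-weight model."""

    weights: dict[AttributeKey, float]
    threshold_T: int
    n_epoch: int
    intercept_C0: float = 0.0
    slope_C1: float = 1.0
    seed: int = 0
    blocked: frozenset = frozenset()
    intercept_se: float | None = None
    slope_se: float | None = None
    trace: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "settings": {
                "threshold_T": self.threshold_T,
                "n_epoch": self.n_epoch,
                "seed": self.seed,
            },
            "intercept": self.intercept_C0,
            "slope": self.slope_C1,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "blocked": sorted(
                [k.category, k.key] for k in self.blocked
            ),
            "weights": [
                [k.category, k.key, w]
                for k, w in sorted(
                    self.weights.items(), key=lambda kv: (kv[0].category, kv[0].key)
                )
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CWModel":
        doc = json.loads(text)
        return cls(
            weights={
                AttributeKey(key, cat): w for cat, key, w in doc["weights"]
            },
            threshold_T=doc["settings"]["threshold_T"],
            n_epoch=doc["settings"]["n_epoch"],
            intercept_C0=doc["intercept"],
            slope_C1=doc["slope"],
            seed=doc["settings"]["seed"],
            blocked=frozenset(
                AttributeKey(key, cat) for cat, key in doc["blocked"]
            ),
            intercept_se=doc.get("intercept_se"),
            slope_se=doc.get("slope_se"),
        )


def make_splits(
    records: list[MoleculeRecord],
    n_splits: int = 3,
    fraction: float = 0.75,
    seed: int = 0,
) -> list[SplitDataset]:
    """Random reproducible train/test splits.

    Training size is round(fraction·N).  Each split carries a ``balance``
    report comparing the activity mean and spread of the two sets.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if any(r.activity is None for r in records):
        raise ValueError("every record needs an observed activity")
    rng = np.random.default_rng(seed)
    n_train = int(round(fraction * len(records)))
    splits = []
    for _ in range(n_splits):
        order = rng.permutation(len(records))
        train = [records[i] for i in sorted(order[:n_train])]
        test = [records[i] for i in sorted(order[n_train:])]
        ytr = np.array([r.activity for r in train])
        yte = np.array([r.activity for r in test])
        balance = {
            "train_mean": float(ytr.mean()), "train_std": float(ytr.std()),
            "test_mean": float(yte.mean()), "test_std": float(yte.std()),
            "mean_gap": float(abs(ytr.mean() - yte.mean())),
        }
        splits.append(SplitDataset(train, test, balance))
    return splits


def block_rare(profiles: list[AttributeProfile], T: int) -> frozenset:
    """Keys present in fewer than T molecules of the training set."""
    if T < 1:
        raise ValueError("T must be >= 1")
    n_mols: dict[AttributeKey, int] = {}
    for prof in profiles:
        for key in prof.keys():
            n_mols[key] = n_mols.get(key, 0) + 1
    return frozenset(k for k, n in n_mols.items() if n < T)


def dcw(profile: AttributeProfile, model: CWModel) -> float:
    """Descriptor sum Σ count·CW(key); blocked/unknown keys contribute 0."""
    total = 0.0
    for key, count in profile.counts.items():
        if key in model.blocked:
            continue
        total += count * model.weights.get(key, 0.0)
    return total


def calibrate(dcw_values, activities) -> tuple[float, float, float, float]:
    """OLS calibration line: (C0, C1, se_C0, se_C1)."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(activities, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("calibration needs >= 2 distinct DCW values")
    fit = stats.linregress(x, y)
    return (
        float(fit.intercept), float(fit.slope),
        float(fit.intercept_stderr), float(fit.stderr),
    )


def predict(model: CWModel, profile: AttributeProfile) -> float:
    """pKi prediction C0 + C1·DCW."""
    return model.intercept_C0 + model.slope_C1 * dcw(profile, model)


def predict_smiles(model: CWModel, smiles: str) -> float:
    return predict(model, profile_for(smiles))


def _target(dcw_vec, y, iic_weight: float) -> float:
    sx = dcw_vec.std()
    if sx == 0:
        return -np.inf
    r = float(np.corrcoef(dcw_vec, y)[0, 1])
    r2 = r * r
    if iic_weight == 0.0:
        return r2
    slope, intercept = np.polyfit(dcw_vec, y, 1)
    iic_val, _ = _iic_metric(y, intercept + slope * dcw_vec)
    return (1.0 - iic_weight) * r2 + iic_weight * iic_val


def optimize(
    split: SplitDataset,
    T: int,
    n_epoch: int,
    seed: int = 0,
    move_scale: float = 0.1,
    iic_weight: float = 0.0,
    init: str = "ones",
    proposals_per_visit: int = 10,
) -> CWModel:
    """Greedy Monte Carlo optimization of the correlation weights.

    Starting from CW = 1 for every active key (or a seeded uniform start),
    each epoch visits the active keys in random order; at each visit a short
    sequence of ``proposals_per_visit`` perturbations δ ~ U(−move_scale,
    move_scale) is proposed one at a time, each accepted iff the training
    target does not decrease.  The accepted-target trace is kept on the
    returned model; the final calibration line is refitted by OLS.
    """
    profiles = [profile_for(r.smiles) for r in split.training]
    y = np.array([r.activity for r in split.training], dtype=float)
    blocked = block_rare(profiles, T)
    vocab = sorted(
        {k for p in profiles for k in p.keys()} - blocked,
        key=lambda k: (k.category, k.key),
    )
    if not vocab:
        raise ValueError("no active attributes after rarity blocking")
    col = {k: j for j, k in enumerate(vocab)}
    X = np.zeros((len(profiles), len(vocab)))
    for i, prof in enumerate(profiles):
        for key, count in prof.counts.items():
            j = col.get(key)
            if j is not None:
                X[i, j] = count

    rng = np.random.default_rng(seed)
    if init == "ones":
        w = np.ones(len(vocab))
    elif init == "uniform":
        w = rng.uniform(-1.0, 1.0, size=len(vocab))
    else:
        raise ValueError(f"unknown init {init!r}")

    dcw_vec = X @ w
    current = _target(dcw_vec, y, iic_weight)
    trace = [current]
    for _ in range(n_epoch):
        for j in rng.permutation(len(vocab)):
            for delta in rng.uniform(-move_scale, move_scale,
                                     size=proposals_per_visit):
                cand = dcw_vec + delta * X[:, j]
                t_new = _target(cand, y, iic_weight)
                if t_new >= current:
                    w[j] += delta
                    dcw_vec = cand
                    current = t_new
                    trace.append(current)

    C0, C1, se0, se1 = calibrate(dcw_vec, y)
    return CWModel(
        weights={k: float(w[j]) for k, j in col.items()},
        threshold_T=T, n_epoch=n_epoch,
        intercept_C0=C0, slope_C1=C1, seed=seed,
        blocked=blocked, intercept_se=se0, slope_se=se1, trace=trace,
    )


def evaluate_r2(model: CWModel, records: list[MoleculeRecord]) -> float:
    """Squared correlation between observed and predicted activity."""
    y = np.array([r.activity for r in records], dtype=float)
    p = np.array([predict_smiles(model, r.smiles) for r in records])
    if p.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(y, p)[0, 1]) ** 2


class CorrelationWeightRegressor(RegressorMixin, BaseEstimator):
    """SMILES-in, activity-out regressor built on correlation weights.

    Parameters
    ----------
    threshold : int
        Rarity threshold T; attributes in fewer than T training molecules
        are blocked.
    n_epoch : int
        Monte Carlo optimization epochs.
    move_scale : float
        Half-width of the uniform weight-perturbation proposal, in
        activity-contribution units.
    iic_weight : float
        Blend weight of the index of ideality of correlation in the
        optimization target (0 = plain training r²).
    init : str
        'ones' (deterministic) or 'uniform' start for the weights.
    random_state : int
        Seed for the Monte Carlo search.
    """

    def __init__(self, threshold: int = 1, n_epoch: int = 15,
                 move_scale: float = 0.1, iic_weight: float = 0.0,
                 init: str = "ones", random_state: int = 0):
        self.threshold = threshold
        self.n_epoch = n_epoch
        self.move_scale = move_scale
        self.iic_weight = iic_weight
        self.init = init
        self.random_state = random_state

    def fit(self, X, y):
        """Fit on a sequence of SMILES strings and activities."""
        records = [
            MoleculeRecord(str(i), smiles, float(a))
            for i, (smiles, a) in enumerate(zip(X, y))
        ]
        split = SplitDataset(records, [])
        self.model_ = optimize(
            split, T=self.threshold, n_epoch=self.n_epoch,
            seed=self.random_state, move_scale=self.move_scale,
            iic_weight=self.iic_weight, init=self.init,
        )
        self.weights_ = self.model_.weights
        self.blocked_ = self.model_.blocked
        self.intercept_ = self.model_.intercept_C0
        self.slope_ = self.model_.slope_C1
        self.trace_ = self.model_.trace
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("estimator is not fitted")
        return np.array([predict_smiles(self.model_, s) for s in X])
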