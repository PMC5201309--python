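"""Hansch-style 2D QSAR: physicochemical descriptors, correlation-based
descriptor selection, maximin diverse train/test splitting, ordinary
least-squares fitting with exact leave-one-out validation, and lipophilic
efficiency.

The published single-descriptor activity model shipped here relates
log(1/IC50[μM]) to Wildman–Crippen molar refractivity:

    log(1/IC50) = −3.52250 + 0.23173 · MR

Its coefficients are constants of this module (re-deriving them would
require the original descriptor software); everything else is computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Crippen

from .chem_io import Molecule, molecule_to_rdkit
from .modeling import ModelStats

log = logging.getLogger(__name__)

__all__ = [
    "DescriptorVector",
    "HANSCH_INTERCEPT",
    "HANSCH_MR_COEF",
    "compute_mr",
    "compute_descriptors",
    "hansch_predict",
    "fit_mlr",
    "contingency_select",
    "diverse_split",
    "lipe",
]

HANSCH_INTERCEPT = -3.52250
HANSCH_MR_COEF = 0.23173


@dataclass
class DescriptorVector:
    mr: float
    logp: float
    extras: dict[str, float]

    def __post_init__(self):
        vals = [self.mr, self.logp, *self.extras.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("descriptor values must be finite")


def compute_mr(m: Molecule) -> float:
    """Wildman–Crippen additive molar refractivity (SMR)."""
    rd = molecule_to_rdkit(m)
    try:
        rd.UpdatePropertyCache(strict=False)
        return float(Crippen.MolMR(rd))
    except Exception as exc:
        elements = sorted({a.element for a in m.atoms})
        raise ValueError(
            f"MR contribution unavailable for molecule {m.id!r} (elements {elements})"
        ) from exc


def compute_descriptors(m: Molecule) -> DescriptorVector:
    rd = molecule_to_rdkit(m)
    rd.UpdatePropertyCache(strict=False)
    logp, mr = Crippen.MolLogP(rd), Crippen.MolMR(rd)
    heavy = sum(1 for a in m.atoms if a.element != "H")
    return DescriptorVector(mr=float(mr), logp=float(logp),
                            extras={"heavy_atoms": float(heavy)})


def hansch_predict(mr: float) -> float:
    """Predicted log(1/IC50[μM]) from molar refractivity via the shipped
    single-descriptor model."""
    if not math.isfinite(mr):
        raise ValueError(f"MR must be finite, got {mr}")
    return HANSCH_INTERCEPT + HANSCH_MR_COEF * mr


def lipe(ic50_um: float, clogp: float) -> float:
    """Lipophilic efficiency: pIC50 (molar) − clogP = (6 − log10(IC50[μM])) − clogP."""
    if ic50_um <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_um}")
    return (6.0 - math.log10(ic50_um)) - clogp


def fit_mlr(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ModelStats]:
    """Ordinary least squares with intercept; exact LOO q² via the hat-matrix
    identity e_(−i) = e_i / (1 − h_ii), which equals refitting without row i.

    Returns (coefficients with intercept last, ModelStats).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 rows (n={n}, p={p})")
    stds = X.std(axis=0)
    if np.any(stds <= 1e-12):
        bad = np.flatnonzero(stds <= 1e-12).tolist()
        raise ValueError(f"constant descriptor column(s) {bad}: run descriptor selection")

    Xd = np.column_stack([X, np.ones(n)])
    rank = np.linalg.matrix_rank(Xd)
    if rank < p + 1:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {p + 1}): reduce collinearity "
            "with descriptor selection"
        )
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    yhat = Xd @ beta
    resid = y - yhat
    sse = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())

    H_diag = np.einsum("ij,ji->i", Xd, np.linalg.pinv(Xd))
    loo_resid = resid / (1.0 - H_diag)
    press = float(loo_resid @ loo_resid)

    stats = ModelStats(
        r2=1.0 - sse / ss_tot,
        q2_loo=1.0 - press / ss_tot,
        rmse=float(np.sqrt(sse / n)),
        n=n,
        sdep=float(np.sqrt(press / n)),
        sdep_nm1=float(np.sqrt(press / (n - 1))),
    )
    return beta, stats


def contingency_select(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Rank descriptors by |Pearson correlation| with y and return the top-k
    column indices (a transparent stand-in for proprietary contingency
    scoring). Constant columns score 0; ties break on the lower index."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k > p:
        raise ValueError(f"k={k} exceeds descriptor count {p}")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    scores = np.zeros(p)
    for j in range(p):
        xc = X[:, j] - X[:, j].mean()
        sx = np.sqrt((xc**2).sum())
        if sx > 1e-12 and sy > 1e-12:
            scores[j] = abs(float(xc @ yc) / (sx * sy))
    # stable sort on (-score, index): lower index wins ties
    order = np.lexsort((np.arange(p), -scores))
    return np.sort(order[:k])


def diverse_split(
    X: np.ndarray, test_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Maximin diverse subset selection of the test set.

    Descriptors are z-scored; the first test pick is the point with maximal
    mean Euclidean distance to all others, and each subsequent pick maximizes
    its minimum distance to the already-chosen set. Test size is
    floor(test_fraction · n). Deterministic (the seed only breaks exact
    ties, which cannot occur for generic real descriptors).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"diverse split needs at least 5 rows, got {n}")
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n_test = int(np.floor(test_fraction * n))
    if n_test < 1:
        raise ValueError(f"test fraction {test_fraction} selects no rows at n={n}")

    stds = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(stds > 1e-12, stds, 1.0)
    D = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)

    rng = np.random.default_rng(seed)
    mean_d = D.mean(axis=1)
    start_candidates = np.flatnonzero(mean_d >= mean_d.max() - 1e-12)
    first = int(start_candidates[0]) if len(start_candidates) == 1 else int(
        rng.choice(start_candidates)
    )
    test = [first]
    dmin = D[first].copy()
    dmin[first] = -np.inf
    while len(test) < n_test:
        candidates = np.flatnonzero(dmin >= dmin.max() - 1e-12)
        nxt = int(candidates[0]) if len(candidates) == 1 else int(rng.choice(candidates))
        test.append(nxt)
        np.minimum(dmin, D[nxt], out=dmin)
        dmin[nxt] = -np.inf
    test_idx = np.array(sorted(test))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx
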