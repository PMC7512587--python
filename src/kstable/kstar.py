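"""K* instance-based classifier over mixed symbolic/numeric features.

K* is a lazy learner: training stores the instances, and classification
sums, per class, the probabilities of *transforming* the query into each
stored instance.  Per attribute the transformation model is entropic:

* symbolic attribute with stop probability ``s`` and training symbol
  frequencies ``freq``:  P(a→b) = s·freq(b) for b ≠ a and
  P(a→a) = (1−s) + s·freq(a)  (rows sum to 1);
* numeric attribute with scale ``x0``: weight ∝ exp(−|Δ| / x0),
  the discrete exponential kernel over the stored values.

The free parameter per (query, attribute) — ``s`` or ``x0`` — is picked by
the *blend* setting b ∈ [0, 100]: it is the value at which the effective
number of participating instances, n_eff = (Σw)² / Σw², equals
``n_lo + (b/100)(N − n_lo)``, where n_lo is the x0→0 (or s→0) limit, i.e.
the count of nearest/matching instances.  b = 0 reduces to nearest
neighbours, b = 100 to uniform weighting; both limits are applied
analytically.  The solver bisects on log x0 (or on s), and clamps s to
[0, 1] when the target count is unreachable.

Per-instance probability is the product of per-attribute probabilities
(accumulated in log space); class probability is the normalized sum over
that class's instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .attributes import KIND_BASIS_SYMBOLIC, FeatureMatrix, FeatureSchema
from .dataset import NEGATIVE
from .errors import KStarError


@dataclass(frozen=True)
class KStarConfig:
    """K* hyperparameters.

    blend:
        Sphere-of-influence setting in [0, 100]; 0 = nearest neighbour,
        100 = uniform over all instances.  Default 20.
    scale_tolerance:
        Relative tolerance (fraction of N) for the effective-count root
        finding.
    max_bisect_iters:
        Iteration cap for bracketing + bisection.
    tie_break:
        Class returned on an exact probability tie (default the
        destabilizing / majority class).
    """

    blend: float = 20.0
    scale_tolerance: float = 1e-6
    max_bisect_iters: int = 200
    tie_break: str = NEGATIVE

    def __post_init__(self) -> None:
        if not (0.0 <= self.blend <= 100.0):
            raise KStarError(f"blend must be in [0, 100], got {self.blend}")
        if self.scale_tolerance <= 0:
            raise KStarError("scale_tolerance must be positive")


def effective_count(weights) -> float:
    """n_eff = (Σw)² / Σw² of a non-negative weight vector."""
    w = np.asarray(weights, dtype=float)
    s2 = float(np.sum(w * w))
    if s2 == 0.0:
        return 0.0
    return float(np.sum(w)) ** 2 / s2


def symbolic_transform_prob(a: str, b: str, s: float, freqs: Mapping[str, float]) -> float:
    """Entropic symbolic transformation probability P(a→b)."""
    if not (0.0 <= s <= 1.0):
        raise KStarError(f"stop probability s must be in [0, 1], got {s}")
    fb = float(freqs.get(b, 0.0))
    if a == b:
        return (1.0 - s) + s * fb
    return s * fb


def _neff_rows(w: np.ndarray) -> np.ndarray:
    s1 = w.sum(axis=1)
    s2 = (w * w).sum(axis=1)
    out = np.zeros_like(s1)
    nz = s2 > 0
    out[nz] = s1[nz] ** 2 / s2[nz]
    return out


def _solve_x0_batch(
    D: np.ndarray, blend: float, tol: float, max_iters: int
) -> np.ndarray:
    """Per-row scale x0 for a Q×N matrix of |query − training| distances.

    Works on row-shifted distances (invariant of n_eff), bisecting on a
    geometric grid.  Assumes 0 < blend < 100.
    """
    Q, N = D.shape
    dmin = D.min(axis=1, keepdims=True)
    Ds = D - dmin
    n_lo = (Ds == 0.0).sum(axis=1).astype(float)
    target = n_lo + (blend / 100.0) * (N - n_lo)
    atol = max(tol * N, 1e-12)
    spread = Ds.max(axis=1)
    x0 = np.ones(Q)
    active = (spread > 0) & (N - n_lo > 0)
    if not np.any(active):
        return x0
    Da = Ds[active]
    tgt = target[active]

    def neff(x):
        return _neff_rows(np.exp(-Da / x[:, None]))

    # Smallest nonzero shifted distance per row seeds the lower bracket.
    pos = np.where(Da > 0, Da, np.inf)
    lo = pos.min(axis=1) * 1e-3
    hi = Da.max(axis=1) * 2.0
    for _ in range(max_iters):
        mask = neff(hi) < tgt - atol
        if not mask.any():
            break
        hi[mask] *= 4.0
    for _ in range(max_iters):
        mask = neff(lo) > tgt + atol
        if not mask.any():
            break
        lo[mask] /= 4.0
    sol = np.sqrt(lo * hi)
    converged = np.zeros(len(sol), dtype=bool)
    for _ in range(max_iters):
        ne = neff(sol)
        converged = np.abs(ne - tgt) <= atol
        if converged.all():
            break
        too_low = ne < tgt
        lo = np.where(too_low & ~converged, sol, lo)
        hi = np.where(~too_low & ~converged, sol, hi)
        sol = np.sqrt(lo * hi)
    if not converged.all():
        i = int(np.argmax(~converged))
        raise KStarError(
            f"numeric scale solver did not converge within {max_iters} "
            f"iterations (bracket [{lo[i]:.3g}, {hi[i]:.3g}], "
            f"target n_eff {tgt[i]:.6g})"
        )
    x0[active] = sol
    return x0


def numeric_scale_solve(
    query_value: float,
    training_values,
    blend: float,
    tol: float = 1e-6,
    max_iters: int = 200,
) -> float:
    """Solve the per-query scale x0 for one numeric attribute.

    Returns x0 such that the effective instance count of the weights
    exp(−|v − query| / x0) equals n_lo + (blend/100)(N − n_lo) within
    ``tol·N``, where n_lo is the count of minimum-distance instances.
    For blend 0 / 100 the returned scale realizes the corresponding limit
    to within the same tolerance.
    """
    t = np.asarray(training_values, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise KStarError("training_values must be a non-empty 1-D vector")
    D = np.abs(t - float(query_value))[None, :]
    if blend <= 0.0:
        # Shrink towards the nearest-neighbour limit explicitly.
        spread = float(D.max() - D.min())
        if spread == 0.0:
            return 1.0
        pos = D[D > D.min()]
        gap = float(pos.min() - D.min())
        # exp(-gap/x0) ≤ tol makes non-nearest weight negligible.
        return gap / max(np.log(1.0 / max(tol, 1e-300)), 1.0)
    if blend >= 100.0:
        spread = float(D.max() - D.min())
        if spread == 0.0:
            return 1.0
        return spread / max(tol, 1e-300) ** 0.5  # flat enough for n_eff ≈ N
    return float(_solve_x0_batch(D, blend, tol, max_iters)[0])


def _solve_s_batch(
    match: np.ndarray, fvec: np.ndarray, blend: float, tol: float, max_iters: int
) -> np.ndarray:
    """Per-row stop probability s for one symbolic attribute.

    ``match`` is Q×N (query symbol == training symbol), ``fvec`` the
    training-frequency of each training instance's symbol.  s is clamped
    to [0, 1] when the target effective count is unreachable.
    """
    Q, N = match.shape
    m = match.sum(axis=1).astype(float)
    target = m + (blend / 100.0) * (N - m)
    atol = max(tol * N, 1e-12)
    s = np.ones(Q)
    f = fvec[None, :]

    def neff(sv):
        w = sv[:, None] * f + (1.0 - sv)[:, None] * match
        return _neff_rows(w)

    # No matching instance: weights ∝ fvec for every s > 0; s is immaterial.
    solvable = m > 0
    if blend <= 0.0:
        s[solvable] = 0.0
        return s
    if blend >= 100.0:
        return s  # clamp at the most uniform reachable weighting
    hi_ne = neff(np.ones(Q))
    lo_ne = m  # n_eff at s = 0
    s[solvable & (hi_ne <= target + atol)] = 1.0
    todo = solvable & (hi_ne > target + atol) & (lo_ne < target - atol)
    s[solvable & (lo_ne >= target - atol) & (hi_ne > target + atol)] = 0.0
    if not todo.any():
        return s
    lo = np.zeros(int(todo.sum()))
    hi = np.ones(int(todo.sum()))
    match_t = match[todo]
    tgt = target[todo]

    def neff_t(sv):
        w = sv[:, None] * fvec[None, :] + (1.0 - sv)[:, None] * match_t
        return _neff_rows(w)

    sol = 0.5 * (lo + hi)
    for _ in range(max_iters):
        ne = neff_t(sol)
        if np.all(np.abs(ne - tgt) <= atol):
            break
        too_low = ne < tgt
        lo = np.where(too_low, sol, lo)
        hi = np.where(~too_low, sol, hi)
        sol = 0.5 * (lo + hi)
    s[todo] = sol
    return s


class KStarClassifier:
    """Lazy K* classifier; ``fit`` stores the instances, nothing more."""

    def __init__(self, config: KStarConfig | None = None):
        self.config = config or KStarConfig()
        self._frame: pd.DataFrame | None = None
        self._target: np.ndarray | None = None
        self._schema: FeatureSchema | None = None
        self._freqs: dict[str, dict[str, float]] = {}
        self.classes_: tuple[str, ...] = ()

    @property
    def is_fitted(self) -> bool:
        return self._frame is not None

    @property
    def n_instances(self) -> int:
        return 0 if self._frame is None else len(self._frame)

    def fit(self, matrix: FeatureMatrix) -> "KStarClassifier":
        if len(matrix) == 0:
            raise KStarError("cannot fit K* on an empty feature matrix")
        self._frame = matrix.frame.reset_index(drop=True)
        self._target = np.asarray(matrix.target, dtype=object)
        self._schema = matrix.schema
        self.classes_ = tuple(sorted({str(c) for c in self._target}))
        self._freqs = {}
        for name in matrix.schema.symbolic_names:
            counts = self._frame[name].value_counts(normalize=True)
            self._freqs[name] = {str(k): float(v) for k, v in counts.items()}
        return self

    # -- prediction ------------------------------------------------------

    def _query_frame(self, queries) -> pd.DataFrame:
        if isinstance(queries, FeatureMatrix):
            frame = queries.frame
        elif isinstance(queries, pd.DataFrame):
            frame = queries
        else:
            raise KStarError("queries must be a FeatureMatrix or DataFrame")
        expected = list(self._schema.names)
        if sorted(frame.columns) != sorted(expected):
            raise KStarError(
                f"query schema mismatch: expected columns {expected}, "
                f"got {list(frame.columns)}")
        return frame[expected]

    def _log_weights(self, frame: pd.DataFrame) -> np.ndarray:
        cfg = self.config
        Q, N = len(frame), self.n_instances
        logW = np.zeros((Q, N))
        with np.errstate(divide="ignore"):
            for name in self._schema.names:
                kind = self._schema.descriptors[name].kind
                if kind == KIND_BASIS_SYMBOLIC:
                    tr = self._frame[name].to_numpy(dtype=object)
                    qs = frame[name].to_numpy(dtype=object)
                    freqs = self._freqs[name]
                    fvec = np.array([freqs.get(str(v), 0.0) for v in tr])
                    match = qs[:, None] == tr[None, :]
                    s = _solve_s_batch(match, fvec, cfg.blend,
                                       cfg.scale_tolerance, cfg.max_bisect_iters)
                    w = s[:, None] * fvec[None, :] + (1.0 - s)[:, None] * match
                    logW += np.log(w)
                else:
                    tr = self._frame[name].to_numpy(dtype=float)
                    qs = frame[name].to_numpy(dtype=float)
                    D = np.abs(qs[:, None] - tr[None, :])
                    if cfg.blend >= 100.0:
                        continue  # uniform weights: no contribution
                    if cfg.blend <= 0.0:
                        dmin = D.min(axis=1, keepdims=True)
                        logW += np.where(D == dmin, 0.0, -np.inf)
                        continue
                    x0 = _solve_x0_batch(D, cfg.blend, cfg.scale_tolerance,
                                         cfg.max_bisect_iters)
                    dmin = D.min(axis=1, keepdims=True)
                    logW += -(D - dmin) / x0[:, None]
        return logW

    def predict_proba(self, queries) -> pd.DataFrame:
        """Class-probability distribution per query row."""
        if not self.is_fitted:
            raise KStarError("classifier is not fitted")
        frame = self._query_frame(queries)
        logW = self._log_weights(frame)
        cols = {}
        for c in self.classes_:
            mask = self._target == c
            if mask.any():
                cols[c] = logsumexp(logW[:, mask], axis=1)
            else:
                cols[c] = np.full(len(frame), -np.inf)
        logp = np.column_stack([cols[c] for c in self.classes_])
        out = np.empty_like(logp)
        finite = np.isfinite(logp).any(axis=1)
        # Total mass zero (possible at blend 0 with unmatched symbols):
        # fall back to the training class priors.
        priors = np.array([float(np.mean(self._target == c)) for c in self.classes_])
        out[~finite] = priors
        if finite.any():
            z = logsumexp(logp[finite], axis=1, keepdims=True)
            out[finite] = np.exp(logp[finite] - z)
        return pd.DataFrame(out, columns=list(self.classes_))

    def predict(self, queries) -> np.ndarray:
        """Most probable class per query; exact ties go to the tie class."""
        probs = self.predict_proba(queries)
        arr = probs.to_numpy()
        labels = []
        classes = list(self.classes_)
        tie_class = self.config.tie_break if self.config.tie_break in classes else classes[0]
        for row in arr:
            top = row.max()
            tied = [c for c, p in zip(classes, row) if abs(p - top) <= 1e-12]
            labels.append(tie_class if len(tied) > 1 and tie_class in tied else
                          classes[int(np.argmax(row))])
        return np.array(labels, dtype=object)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Persist the model as a single JSON archive (text, lossless floats)."""
        if not self.is_fitted:
            raise KStarError("cannot save an unfitted classifier")
        payload = {
            "config": {
                "blend": self.config.blend,
                "scale_tolerance": self.config.scale_tolerance,
                "max_bisect_iters": self.config.max_bisect_iters,
                "tie_break": self.config.tie_break,
            },
            "schema": json.loads(self._schema.to_json()),
            "columns": list(self._frame.columns),
            "data": [list(row) for row in self._frame.itertuples(index=False)],
            "target": [str(t) for t in self._target],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "KStarClassifier":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        config = KStarConfig(**payload["config"])
        schema = FeatureSchema.from_json(json.dumps(payload["schema"]))
        frame = pd.DataFrame(payload["data"], columns=payload["columns"])
        for n in schema.symbolic_names:
            frame[n] = frame[n].astype(object)
        for n in schema.numeric_names:
            frame[n] = frame[n].astype(float)
        matrix = FeatureMatrix(frame[list(schema.names)],
                               np.array(payload["target"], dtype=object), schema)
        return cls(config).fit(matrix)
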