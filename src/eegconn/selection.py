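"""Feature ranking by Orthogonal Forward Regression with a random-probe stop.

OFR greedily ranks candidate features: at each step the feature whose
squared cosine with the current residual output is largest is selected, the
output is projected onto the null space of that feature, and the remaining
candidates are Gram-Schmidt-orthogonalized against it.  The random-probe
technique turns the ranking into a selection: many realizations of a pure
noise "probe" feature are ranked alongside the real candidates, and a real
feature at step k is accepted only while the probability that a probe ranks
at or before step k stays below the chosen risk (default 10%).

Selection is applied in two stages: within each frequency band first, then
on the pooled survivors across bands, so that the final feature set can mix
bands while redundant cross-band duplicates are removed by the
orthogonalization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureDescriptor",
    "FeatureTable",
    "ProbeResult",
    "SelectionResult",
    "ofr_rank",
    "probe_ranks",
    "probe_select",
    "two_stage_select",
]

_COLLINEAR_TOL = 1e-10


@dataclass(frozen=True)
class FeatureDescriptor:
    """What a feature column measures: band, electrode, graph parameter, PT."""

    band: str
    electrode: str
    graph_param: str
    pt: float

    @property
    def name(self) -> str:
        return f"{self.band}_{self.electrode}_{self.graph_param}_{self.pt:g}"

    @classmethod
    def parse(cls, name: str) -> "FeatureDescriptor":
        band, electrode, param, pt = name.rsplit("_", 3)[-4:]
        return cls(band, electrode, param, float(pt))


@dataclass
class FeatureTable:
    """Subjects x features matrix with descriptors and binary labels."""

    matrix: np.ndarray
    descriptors: list
    labels: np.ndarray

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains NaN or Inf")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length does not match subject count")
        if self.matrix.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count does not match feature count")
        if len(np.unique(self.labels)) > 2:
            raise ValueError("labels must be binary")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = [d.name if isinstance(d, FeatureDescriptor) else str(d)
                for d in self.descriptors]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "label", self.labels.astype(int))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        import pandas as pd

        df = pd.read_csv(path)
        labels = df.pop("label").values
        descs = []
        for c in df.columns:
            try:
                descs.append(FeatureDescriptor.parse(c))
            except (ValueError, IndexError):
                descs.append(c)
        return cls(df.values, descs, labels)


@dataclass
class ProbeResult:
    """Empirical distribution of the probe feature's rank."""

    n_probes: int
    ranks: np.ndarray  # rank (1-based) attained by each probe realization
    risk: float

    def cdf(self, step: int) -> float:
        """P(probe rank <= step); a tie counts as the probe winning."""
        return float(np.mean(self.ranks <= step))


@dataclass
class SelectionResult:
    """Ranked features, the accepted prefix, and the stopping evidence."""

    ranked: list  # descriptors in OFR order
    scores: list  # squared residual correlation at selection time
    selected: list  # accepted prefix of `ranked`
    stage: str = "per_band"
    probe: ProbeResult | None = None
    per_band: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json(self, path) -> None:
        def _name(d):
            return d.name if isinstance(d, FeatureDescriptor) else str(d)

        doc = {
            "stage": self.stage,
            "ranked": [_name(d) for d in self.ranked],
            "scores": [float(s) for s in self.scores],
            "selected": [_name(d) for d in self.selected],
            "stopping_step": len(self.selected),
        }
        if self.probe is not None:
            doc["probe"] = {
                "n_probes": self.probe.n_probes,
                "risk": self.probe.risk,
            }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _center(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def ofr_rank(matrix, labels, max_steps: int | None = None):
    """Rank feature columns by OFR; returns (order, scores).

    ``order`` holds original column indices in decreasing relevance;
    ``scores`` the squared cosine between the (orthogonalized) feature and
    the residual output at the step it was selected.  Zero-variance columns
    are dropped with a warning; columns that become numerically collinear
    with already-selected features are skipped silently.
    """
    X = _center(np.atleast_2d(np.asarray(matrix, dtype=float)).copy())
    y = _center(np.asarray(labels, dtype=float).copy())
    n, p = X.shape
    norms0 = np.linalg.norm(X, axis=0)
    alive = norms0 > 0
    if not np.any(alive):
        raise ValueError("all features have zero variance")
    if np.any(~alive):
        warnings.warn(
            f"dropping {int(np.sum(~alive))} zero-variance feature(s)",
            RuntimeWarning,
        )
    order: list[int] = []
    scores: list[float] = []
    steps = max_steps if max_steps is not None else p
    for _ in range(steps):
        ynorm2 = float(y @ y)
        if ynorm2 <= _COLLINEAR_TOL:
            break
        norms2 = np.einsum("ij,ij->j", X, X)
        alive &= norms2 > (_COLLINEAR_TOL * np.maximum(norms0, 1)) ** 2
        if not np.any(alive):
            break
        proj = X.T @ y
        score = np.where(alive, proj**2 / np.maximum(norms2 * ynorm2, 1e-300), -1.0)
        j = int(np.argmax(score))  # ties -> lowest column index
        order.append(j)
        scores.append(float(score[j]))
        f = X[:, j] / np.sqrt(norms2[j])
        y = y - (f @ y) * f
        X = X - np.outer(f, f @ X)
        alive[j] = False
    return order, scores


def probe_ranks(matrix, labels, n_probes: int = 1000, seed: int = 0) -> np.ndarray:
    """Rank attained by each of ``n_probes`` iid standard-normal probes.

    Each probe realization is appended to the candidate set and the whole
    set is ranked by OFR; the probe's 1-based position is recorded.  A probe
    that is never ranked (collinearity exhaustion) counts as rank p+1.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    rng = np.random.default_rng(seed)
    ranks = np.empty(n_probes, dtype=int)
    for b in range(n_probes):
        probe = rng.standard_normal(n)
        aug = np.column_stack([X, probe])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            order, _ = ofr_rank(aug, labels)
        ranks[b] = order.index(p) + 1 if p in order else p + 2
    return ranks


def probe_select(
    table: FeatureTable,
    n_probes: int = 1000,
    risk: float = 0.1,
    seed: int = 0,
    stage: str = "per_band",
) -> SelectionResult:
    """OFR ranking with the random-probe stopping criterion.

    A feature at step k is accepted while the empirical probability that a
    probe attains rank <= k is below ``risk``; the first rejection stops
    the selection.
    """
    if not 0 <= risk < 1:
        raise ValueError("risk must lie in [0, 1)")
    order, scores = ofr_rank(table.matrix, table.labels)
    ranks = probe_ranks(table.matrix, table.labels, n_probes=n_probes, seed=seed)
    probe = ProbeResult(n_probes=n_probes, ranks=ranks, risk=risk)
    n_keep = 0
    for step in range(1, len(order) + 1):
        if probe.cdf(step) < risk:
            n_keep = step
        else:
            break
    ranked = [table.descriptors[j] for j in order]
    return SelectionResult(
        ranked=ranked,
        scores=scores,
        selected=ranked[:n_keep],
        stage=stage,
        probe=probe,
    )


def two_stage_select(
    per_band_tables: dict,
    n_probes: int = 1000,
    risk: float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Per-band probe selection, then a second selection on pooled survivors.

    ``per_band_tables`` maps band name -> :class:`FeatureTable` sharing the
    subject axis and labels.  Stage 2 re-ranks the concatenated selected
    features; its orthogonalization discards duplicates that carry no
    residual information.  An empty stage-1 everywhere yields an empty,
    flagged result.
    """
    per_band: dict[str, SelectionResult] = {}
    cols, descs = [], []
    labels = None
    for k, (band, table) in enumerate(per_band_tables.items()):
        if labels is None:
            labels = table.labels
        elif not np.array_equal(labels, table.labels):
            raise ValueError("per-band tables must share the subject axis/labels")
        res = probe_select(table, n_probes=n_probes, risk=risk, seed=seed + k)
        per_band[band] = res
        for d in res.selected:
            j = table.descriptors.index(d)
            cols.append(table.matrix[:, j])
            descs.append(d)
    if not descs:
        warnings.warn("stage 1 selected nothing in any band", RuntimeWarning)
        return SelectionResult(
            ranked=[], scores=[], selected=[], stage="fused", per_band=per_band
        )
    fused = FeatureTable(np.column_stack(cols), descs, labels)
    res = probe_select(
        fused, n_probes=n_probes, risk=risk, seed=seed + 1000, stage="fused"
    )
    res.per_band = per_band
    return res
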