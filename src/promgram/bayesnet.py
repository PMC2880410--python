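"""Fixed-structure Bayesian network over promoter grammar features.

The model has one Class node (histone vs background) plus 3p - 1 feature
nodes for p motif positions: motif identities M1..Mp, strands S1..Sp and
discretized spacers L2_1..Lp_(p-1).  Every feature node has the Class node
as a parent; in the tree-augmented variant each feature node additionally
has at most one augmenting parent:

* M_i -> M_(i+1)   (a binding site depends on the preceding site, chain
  read from the downstream end),
* M_i -> S_i       (a site's strand depends on the site),
* M_(i+1) -> L_(i+1)_i (a spacer depends on the motif whose placement
  realizes it; a switch selects M_i instead).

Conditional probability tables are estimated by EM: MISSING feature slots
are latent and marginalized, and the M-step applies symmetric-Dirichlet
smoothing, theta = (count + alpha) / (total + alpha * n_states).  Given the
class, the feature graph is a chain of M nodes with S/L leaves, so the
E-step is exact belief propagation (scaled forward-backward) vectorized
over rows sharing a missingness pattern.  The monotone EM objective is the
observed-data log-likelihood plus alpha * sum(log theta) over all table
entries (a Dirichlet(alpha + 1) log-posterior up to an additive constant);
the smoothed update is its exact M-step, so the objective never decreases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import (DEFAULT_BINS, MISSING, FeatureTable, FeatureVector,
                       bin_labels)
from .pwm import ParameterError

CLASS_STATES = ("histone", "background")
STRAND_STATES = ("+", "-")


@dataclass(frozen=True)
class BNStructure:
    """The fixed promoter-grammar network topology.

    ``naive=True`` drops all augmenting edges, leaving a Naive Bayes
    structure.  ``l_parent_outer`` selects M_(i+1) (True, default) or M_i
    as the augmenting parent of L_(i+1)_i.
    """

    n_positions: int = 8
    naive: bool = False
    l_parent_outer: bool = True

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ParameterError("n_positions must be >= 1")

    @property
    def m_nodes(self) -> list[str]:
        return [f"M{i + 1}" for i in range(self.n_positions)]

    @property
    def s_nodes(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_positions)]

    @property
    def l_nodes(self) -> list[str]:
        return [f"L{i + 2}_{i + 1}" for i in range(self.n_positions - 1)]

    @property
    def nodes(self) -> list[str]:
        return ["Class"] + self.m_nodes + self.s_nodes + self.l_nodes

    @property
    def class_edges(self) -> list[tuple[str, str]]:
        return [("Class", n) for n in self.nodes[1:]]

    @property
    def augmenting_edges(self) -> list[tuple[str, str]]:
        if self.naive:
            return []
        edges = [(f"M{i}", f"M{i + 1}") for i in range(1, self.n_positions)]
        edges += [(m, s) for m, s in zip(self.m_nodes, self.s_nodes)]
        for i in range(1, self.n_positions):
            parent = f"M{i + 1}" if self.l_parent_outer else f"M{i}"
            edges.append((parent, f"L{i + 1}_{i}"))
        return edges

    @property
    def edges(self) -> list[tuple[str, str]]:
        return self.class_edges + self.augmenting_edges


def build_structure(n_positions: int = 8, naive: bool = False,
                    l_parent_outer: bool = True) -> BNStructure:
    """Construct the fixed network topology (Naive Bayes if ``naive``)."""
    return BNStructure(n_positions, naive, l_parent_outer)


@dataclass
class BNModel:
    """A fitted grammar network: structure, state spaces and CPTs.

    CPT shapes (C = 2 classes, K = motifs, B = spacer bins):
    ``class`` (C,); ``M1`` (C, K); ``Mi`` i>=2: (C, K, K) augmented or
    (C, K) naive; ``Si``: (C, K, 2) or (C, 2); ``L(i+1)_i``: (C, K, B) or
    (C, B).  MISSING is latent (marginalized) unless the model was fitted
    with ``missing_as_state=True``, in which case every feature alphabet
    carries an explicit absent state.
    """

    structure: BNStructure
    motif_states: list[str]
    spacer_states: list[str]
    cpts: dict[str, np.ndarray]
    alpha: float = 1.0
    missing_as_state: bool = False
    class_states: tuple[str, str] = CLASS_STATES
    strand_states: tuple[str, str] = STRAND_STATES
    spacer_bins: tuple[float, ...] = DEFAULT_BINS

    @property
    def class_prior(self) -> np.ndarray:
        return self.cpts["class"]

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_positions": self.structure.n_positions,
            "naive": self.structure.naive,
            "l_parent_outer": self.structure.l_parent_outer,
            "motif_states": self.motif_states,
            "spacer_states": self.spacer_states,
            "class_states": list(self.class_states),
            "strand_states": list(self.strand_states),
            "spacer_bins": ["inf" if np.isinf(b) else b
                            for b in self.spacer_bins],
            "alpha": self.alpha,
            "missing_as_state": self.missing_as_state,
            "cpts": {k: v.tolist() for k, v in self.cpts.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "BNModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            structure=BNStructure(obj["n_positions"], obj["naive"],
                                  obj["l_parent_outer"]),
            motif_states=obj["motif_states"],
            spacer_states=obj["spacer_states"],
            cpts={k: np.array(v) for k, v in obj["cpts"].items()},
            alpha=obj["alpha"],
            missing_as_state=obj["missing_as_state"],
            class_states=tuple(obj["class_states"]),
            strand_states=tuple(obj["strand_states"]),
            spacer_bins=tuple(np.inf if b == "inf" else float(b)
                              for b in obj["spacer_bins"]),
        )


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def _index_map(states: Sequence[str]) -> dict[str, int]:
    return {s: i for i, s in enumerate(states)}


def _encode_rows(
    rows: Sequence[FeatureVector],
    motif_states: Sequence[str],
    spacer_states: Sequence[str],
    strand_states: Sequence[str] = STRAND_STATES,
    class_states: Sequence[str] | None = None,
    missing_as_state: bool = False,
):
    """Integer-encode feature vectors; -1 marks a latent (MISSING) slot."""
    p = len(rows[0].M)
    m_map = _index_map(motif_states)
    s_map = _index_map(strand_states)
    l_map = _index_map(spacer_states)
    if missing_as_state:
        # explicit absent state appended to each feature alphabet
        m_map = {**m_map, MISSING: len(motif_states)}
        s_map = {**s_map, MISSING: len(strand_states)}
        l_map = {**l_map, MISSING: len(spacer_states)}
    n = len(rows)
    M = np.full((n, p), -1, dtype=np.int32)
    S = np.full((n, p), -1, dtype=np.int32)
    L = np.full((n, max(p - 1, 0)), -1, dtype=np.int32)
    y = None
    if class_states is not None:
        c_map = _index_map(class_states)
        y = np.empty(n, dtype=np.int32)
    for r, row in enumerate(rows):
        if y is not None:
            try:
                y[r] = c_map[row.class_label]
            except KeyError:
                raise ParameterError(
                    f"unseen state {row.class_label!r} at node Class")
        for i in range(p):
            for val, arr, mapping, node in (
                (row.M[i], M, m_map, f"M{i + 1}"),
                (row.S[i], S, s_map, f"S{i + 1}"),
            ):
                if val == MISSING and not missing_as_state:
                    continue
                try:
                    arr[r, i] = mapping[val]
                except KeyError:
                    raise ParameterError(
                        f"unseen state {val!r} at node {node}")
        for i in range(p - 1):
            val = row.L[i]
            if val == MISSING and not missing_as_state:
                continue
            try:
                L[r, i] = l_map[val]
            except KeyError:
                raise ParameterError(
                    f"unseen state {val!r} at node L{i + 2}_{i + 1}")
    return y, M, S, L


# ---------------------------------------------------------------------------
# inference: scaled forward-backward on the per-class motif chain
# ---------------------------------------------------------------------------


def _emissions(model: BNModel, c: int, M, S, L) -> np.ndarray:
    """Evidence potentials psi[r, i, m] for a batch of rows, given class c.

    Observed M slots become indicators; observed S/L leaves fold their CPT
    column into the potential of the M position they hang from.  Fully
    latent subtrees contribute 1 (they marginalize out exactly).
    """
    st = model.structure
    p = st.n_positions
    K = len(model.motif_states) + (1 if model.missing_as_state else 0)
    g = M.shape[0]
    psi = np.ones((g, p, K))
    rows = np.arange(g)
    for i in range(p):
        obs = M[:, i] >= 0
        if obs.any():
            ind = np.zeros((g, K))
            ind[rows[obs], M[obs, i]] = 1.0
            psi[:, i, :] = np.where(obs[:, None], ind, psi[:, i, :])
        s_obs = S[:, i] >= 0
        if s_obs.any():
            theta = model.cpts[f"S{i + 1}"][c]
            if st.naive:
                psi[s_obs, i, :] *= theta[S[s_obs, i]][:, None]
            else:
                psi[s_obs, i, :] *= theta[:, S[s_obs, i]].T
    for i in range(p - 1):
        attach = i + 1 if st.l_parent_outer else i
        l_obs = L[:, i] >= 0
        if l_obs.any():
            theta = model.cpts[f"L{i + 2}_{i + 1}"][c]
            if st.naive:
                psi[l_obs, attach, :] *= theta[L[l_obs, i]][:, None]
            else:
                psi[l_obs, attach, :] *= theta[:, L[l_obs, i]].T
    return psi


def _transition(model: BNModel, c: int, i: int, K: int) -> np.ndarray:
    """T[m, m'] = P(M_(i+1) = m' | class c, M_i = m) as a dense matrix."""
    theta = model.cpts[f"M{i + 2}"][c]
    if model.structure.naive:
        return np.broadcast_to(theta[None, :], (K, K))
    return theta


def _forward_backward(model: BNModel, c: int, M, S, L):
    """Exact chain inference for one class over a batch of rows.

    Returns (f, b, gamma, scale, loglik): scaled forward/backward messages,
    node marginals gamma[r, i, m] = P(M_i = m | evidence, class), per-step
    scaling factors and per-row log P(evidence | class).
    """
    st = model.structure
    p = st.n_positions
    psi = _emissions(model, c, M, S, L)
    g, _, K = psi.shape
    f = np.empty((g, p, K))
    scale = np.empty((g, p))
    a = model.cpts["M1"][c][None, :] * psi[:, 0, :]
    scale[:, 0] = a.sum(1)
    f[:, 0, :] = a / scale[:, 0, None]
    for i in range(p - 1):
        T = _transition(model, c, i, K)
        a = (f[:, i, :] @ T) * psi[:, i + 1, :]
        scale[:, i + 1] = a.sum(1)
        f[:, i + 1, :] = a / scale[:, i + 1, None]
    b = np.empty((g, p, K))
    b[:, p - 1, :] = 1.0
    for i in range(p - 2, -1, -1):
        T = _transition(model, c, i, K)
        b[:, i, :] = ((psi[:, i + 1, :] * b[:, i + 1, :]) @ T.T) \
            / scale[:, i + 1, None]
    gamma = f * b
    loglik = np.log(scale).sum(axis=1)
    return f, b, gamma, psi, scale, loglik


def _class_logliks(model: BNModel, M, S, L) -> np.ndarray:
    """log P(evidence | class) for each row and class; shape (n, 2)."""
    out = np.empty((M.shape[0], 2))
    for c in range(2):
        out[:, c] = _forward_backward(model, c, M, S, L)[5]
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _smoothed(counts: np.ndarray, alpha: float) -> np.ndarray:
    return (counts + alpha) / (counts.sum(axis=-1, keepdims=True)
                               + alpha * counts.shape[-1])


def _zero_counts(model: BNModel) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in model.cpts.items()}


def _init_cpts(structure: BNStructure, K: int, B: int, y, M, S, L,
               alpha: float, n_strand: int = 2) -> dict[str, np.ndarray]:
    """Observed-data smoothed counts as the EM starting point."""
    p = structure.n_positions
    cpts: dict[str, np.ndarray] = {}
    cnt = np.bincount(y, minlength=2).astype(float)
    cpts["class"] = _smoothed(cnt, alpha)

    def family(child, parent, k_parent, k_child):
        if structure.naive or parent is None:
            counts = np.zeros((2, k_child))
            ok = child >= 0
            np.add.at(counts, (y[ok], child[ok]), 1.0)
        else:
            counts = np.zeros((2, k_parent, k_child))
            ok = (child >= 0) & (parent >= 0)
            np.add.at(counts, (y[ok], parent[ok], child[ok]), 1.0)
        return _smoothed(counts, alpha)

    cpts["M1"] = family(M[:, 0], None, K, K)
    for i in range(1, p):
        cpts[f"M{i + 1}"] = family(M[:, i], M[:, i - 1], K, K)
    for i in range(p):
        cpts[f"S{i + 1}"] = family(S[:, i], M[:, i], K, n_strand)
    for i in range(p - 1):
        parent_idx = i + 1 if structure.l_parent_outer else i
        cpts[f"L{i + 2}_{i + 1}"] = family(L[:, i], M[:, parent_idx], K, B)
    return cpts


def _log_prior_penalty(model: BNModel) -> float:
    return model.alpha * sum(float(np.log(v).sum())
                             for v in model.cpts.values())


def fit(
    structure: BNStructure,
    table: FeatureTable,
    alpha: float = 1.0,
    em_max_iter: int = 100,
    em_tol: float = 1e-6,
    seed: int | None = None,
    missing_as_state: bool = False,
) -> BNModel:
    """Estimate CPTs from a feature table by EM with Dirichlet smoothing.

    MISSING slots are latent and marginalized during the E-step (unless
    ``missing_as_state``, which makes absence an explicit observed state
    and reduces fitting to one closed-form pass).  On complete data EM
    converges in one iteration to (count + alpha) / (total + alpha * K).
    ``seed`` is accepted for interface symmetry; the default initializer
    (observed-data smoothed counts) is deterministic.
    """
    if not table.rows:
        raise ParameterError("empty feature table")
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    labels = {r.class_label for r in table.rows}
    if set(CLASS_STATES) - labels:
        raise ParameterError(
            f"both classes {CLASS_STATES} must be present; got {sorted(labels)}")
    spacer_states = bin_labels(table.spacer_bins)
    y, M, S, L = _encode_rows(table.rows, table.motif_alphabet, spacer_states,
                              class_states=CLASS_STATES,
                              missing_as_state=missing_as_state)
    K = len(table.motif_alphabet) + (1 if missing_as_state else 0)
    B = len(spacer_states) + (1 if missing_as_state else 0)
    n_strand = 2 + (1 if missing_as_state else 0)
    st = structure
    p = st.n_positions
    cpts = _init_cpts(st, K, B, y, M, S, L, alpha, n_strand)
    model = BNModel(st, list(table.motif_alphabet), spacer_states, cpts,
                    alpha, missing_as_state, spacer_bins=table.spacer_bins)

    # group rows by (class, missingness pattern) so the E-step runs a
    # handful of vectorized chain passes instead of one per row
    patterns: dict[tuple, np.ndarray] = {}
    masks = np.concatenate([M < 0, S < 0, L < 0], axis=1)
    for r in range(len(y)):
        key = (int(y[r]), masks[r].tobytes())
        patterns.setdefault(key, []).append(r)
    groups = [(c, np.asarray(idx)) for (c, _), idx in patterns.items()]

    prev_obj = -np.inf
    n_iter = 0
    for n_iter in range(1, em_max_iter + 1):
        counts = _zero_counts(model)
        np.add.at(counts["class"], y, 1.0)
        total_ll = float(np.log(model.cpts["class"][y]).sum())
        for c, idx in groups:
            Mg, Sg, Lg = M[idx], S[idx], L[idx]
            f, b, gamma, psi, scale, ll = _forward_backward(
                model, c, Mg, Sg, Lg)
            total_ll += float(ll.sum())
            _accumulate(model, counts, c, Mg, Sg, Lg, f, b, gamma, psi,
                        scale)
        obj = total_ll + _log_prior_penalty(model)
        if obj - prev_obj < em_tol and n_iter > 1:
            break
        prev_obj = obj
        if not np.isfinite(obj):
            raise ParameterError("non-finite EM objective")
        model.cpts = {k: _smoothed(v, alpha) for k, v in counts.items()}
    model.n_em_iter = n_iter
    return model


def _accumulate(model: BNModel, counts, c, M, S, L, f, b, gamma, psi, scale):
    """Add one group's expected sufficient statistics into ``counts``."""
    st = model.structure
    p = st.n_positions
    K = gamma.shape[2]
    counts["M1"][c] += gamma[:, 0, :].sum(axis=0)
    for i in range(p - 1):
        if st.naive:
            counts[f"M{i + 2}"][c] += gamma[:, i + 1, :].sum(axis=0)
        else:
            T = model.cpts[f"M{i + 2}"][c]
            v = psi[:, i + 1, :] * b[:, i + 1, :] / scale[:, i + 1, None]
            counts[f"M{i + 2}"][c] += T * (f[:, i, :].T @ v)
    for i in range(p):
        node = f"S{i + 1}"
        _leaf_counts(model, counts, node, c, S[:, i], gamma[:, i, :], st.naive)
    for i in range(p - 1):
        node = f"L{i + 2}_{i + 1}"
        attach = i + 1 if st.l_parent_outer else i
        _leaf_counts(model, counts, node, c, L[:, i], gamma[:, attach, :],
                     st.naive)


def _leaf_counts(model, counts, node, c, child, parent_gamma, naive):
    theta = model.cpts[node][c]
    obs = child >= 0
    if naive:
        if obs.any():
            np.add.at(counts[node][c], child[obs], 1.0)
        n_miss = int((~obs).sum())
        if n_miss:
            counts[node][c] += n_miss * theta
    else:
        if obs.any():
            for s in np.unique(child[obs]):
                sel = obs & (child == s)
                counts[node][c][:, s] += parent_gamma[sel].sum(axis=0)
        if (~obs).any():
            counts[node][c] += parent_gamma[~obs].sum(axis=0)[:, None] * theta


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_proba(model: BNModel, rows: Sequence[FeatureVector]) -> np.ndarray:
    """P(histone | v) for a batch of feature vectors, in log space."""
    if not rows:
        return np.empty(0)
    _, M, S, L = _encode_rows(rows, model.motif_states, model.spacer_states,
                              model.strand_states,
                              missing_as_state=model.missing_as_state)
    ll = _class_logliks(model, M, S, L)
    log_joint = ll + np.log(model.class_prior)[None, :]
    log_norm = np.logaddexp(log_joint[:, 0], log_joint[:, 1])
    return np.exp(log_joint[:, 0] - log_norm)


def posterior(model: BNModel, v: FeatureVector) -> float:
    """Posterior probability that ``v`` belongs to the histone class.

    MISSING nodes are marginalized jointly with their dependents; the two
    class posteriors sum to 1 by construction.
    """
    return float(predict_proba(model, [v])[0])


def classify(model: BNModel, v: FeatureVector, cut: float = 0.5
             ) -> tuple[str, float]:
    """Class call at a posterior cutoff; a tie (posterior == cut) is
    conservatively called background."""
    p = posterior(model, v)
    return (CLASS_STATES[0] if p > cut else CLASS_STATES[1]), p


def sample(model: BNModel, n: int, seed: int | None = None,
           p_missing: float = 0.0) -> FeatureTable:
    """Draw complete rows from the model's joint distribution.

    Optionally masks each position slot (M, S and incident L jointly) to
    MISSING with probability ``p_missing``, for EM exercises.
    """
    rng = np.random.default_rng(seed)
    st = model.structure
    p = st.n_positions
    rows: list[FeatureVector] = []
    motif_states = list(model.motif_states)
    spacer_states = list(model.spacer_states)
    if model.missing_as_state:
        raise ParameterError("sampling expects a latent-missing model")
    for r in range(n):
        c = int(rng.choice(2, p=model.class_prior))
        m_idx = np.empty(p, dtype=int)
        m_idx[0] = rng.choice(len(motif_states), p=model.cpts["M1"][c])
        for i in range(1, p):
            theta = model.cpts[f"M{i + 1}"][c]
            probs = theta if st.naive else theta[m_idx[i - 1]]
            m_idx[i] = rng.choice(len(motif_states), p=probs)
        M, S, L = [], [], []
        for i in range(p):
            theta = model.cpts[f"S{i + 1}"][c]
            probs = theta if st.naive else theta[m_idx[i]]
            M.append(motif_states[m_idx[i]])
            S.append(model.strand_states[int(rng.choice(2, p=probs))])
        for i in range(p - 1):
            theta = model.cpts[f"L{i + 2}_{i + 1}"][c]
            parent = m_idx[i + 1] if st.l_parent_outer else m_idx[i]
            probs = theta if st.naive else theta[parent]
            L.append(spacer_states[int(rng.choice(len(spacer_states),
                                                  p=probs))])
        if p_missing > 0:
            for i in range(p):
                if rng.random() < p_missing:
                    M[i] = MISSING
                    S[i] = MISSING
                    if i > 0:
                        L[i - 1] = MISSING
                    if i < p - 1:
                        L[i] = MISSING
        rows.append(FeatureVector(f"sample{r}", model.class_states[c],
                                  M, S, L))
    return FeatureTable(rows, motif_states, p, model.spacer_bins)
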