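"""Sparse Hopfield "notebook" modeling the hippocampus.

Each experience (x, y) is bound to a freshly drawn random index pattern ξ — a
binary vector over M units with exactly k = round(a·M) active units — by
one-shot Hebbian plasticity:

* recurrent weights accumulate covariance-rule outer products
  (ξ − a)(ξ − a)ᵀ with zero diagonal, making each index an attractor;
* hetero-associative weights bind ξ to the student-layer activations, also
  with the centered rule, so that reading out a perfectly retrieved index
  through the notebook→student weights reproduces the stored (x, y) at unit
  gain (readout scale 1/(aM(1−a))) up to O(√P/M) crosstalk.

Retrieval runs synchronous dynamics: each cycle applies the recurrent weights
and a k-winners-take-all nonlinearity (exactly k units active, ties broken by
a fixed seeded perturbation of magnitude 1e-12), for nine cycles by default.
Random initial states sample stored memories near-uniformly (offline replay);
partial cues through the student→notebook weights drive pattern completion
(cued recall).  Cueing with fresh inputs makes the notebook act as a
nearest-neighbor regressor, which generalizes poorly in high dimension.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from ._rng import child_rng, child_seed
from .teachers import ExampleSet, TeacherSpec, sample_examples

__all__ = [
    "Notebook",
    "encode",
    "complete",
    "sample_reactivations",
    "cued_recall",
    "notebook_errors",
    "nearest_neighbor_errors",
    "save_notebook",
    "load_notebook",
]


class Notebook:
    """Sparse Hopfield associative memory over M binary units.

    Parameters
    ----------
    m : int
        Number of notebook units.
    sparsity : float
        Fraction ``a`` of active units per index pattern.
    n_inputs : int
        Dimension of the student input layer it binds to.
    seed : int
        Controls index-pattern draws and the k-WTA tie-breaking perturbation.
    """

    def __init__(self, m: int, sparsity: float, n_inputs: int, seed: int = 0):
        if not 0 < sparsity < 1:
            raise ValueError("sparsity must be in (0, 1)")
        self.m = int(m)
        self.a = float(sparsity)
        self.k = int(round(self.a * self.m))
        if self.k < 1:
            raise ValueError("sparsity * m must round to at least one active unit")
        self.n_inputs = int(n_inputs)
        self.seed = int(seed)
        self.indices = np.zeros((0, self.m), dtype=np.uint8)
        self.w_rec = np.zeros((self.m, self.m))
        self.w_sn = np.zeros((self.m, self.n_inputs))      # student input -> notebook
        self.w_ns_x = np.zeros((self.n_inputs, self.m))    # notebook -> student input
        self.w_ns_y = np.zeros(self.m)                     # notebook -> student output
        self._stored_x = np.zeros((self.n_inputs, 0))
        self._stored_y = np.zeros(0)
        # fixed tie-breaking perturbation, descending by unit index on exact ties
        tie = child_rng(seed, "tie-break").random(self.m) * 1e-12
        self._tie = tie - np.arange(self.m) * 1e-18

    @property
    def p(self) -> int:
        """Number of stored memories."""
        return self.indices.shape[0]

    # -- encoding --------------------------------------------------------
    def _draw_indices(self, count: int, rng) -> np.ndarray:
        xi = np.zeros((count, self.m), dtype=np.uint8)
        for i in range(count):
            xi[i, rng.choice(self.m, size=self.k, replace=False)] = 1
        return xi

    def encode(self, data: ExampleSet, seed: int | None = None) -> "Notebook":
        """One-shot Hebbian encoding of every example in ``data`` (in place).

        Emits a capacity warning when the stored load is high enough that the
        fixed-point retrieval guarantee may start to fail.
        """
        if data.p < 1:
            raise ValueError("empty example set")
        if data.inputs.shape[0] != self.n_inputs:
            raise ValueError("example input dimension does not match notebook")
        rng = child_rng(self.seed if seed is None else seed, "indices", self.p)
        xi = self._draw_indices(data.p, rng)
        c = xi - self.a
        self.w_rec += c.T @ c
        np.fill_diagonal(self.w_rec, 0.0)
        self.w_sn += c.T @ data.inputs.T  # (M, n)
        self.w_ns_x += data.inputs @ c
        self.w_ns_y += data.outputs @ c
        self.indices = np.vstack([self.indices, xi])
        self._stored_x = np.hstack([self._stored_x, data.inputs])
        self._stored_y = np.concatenate([self._stored_y, data.outputs])
        if self.p * self.a > 0.25 * self.m * self.a * (1 - self.a):
            warnings.warn(f"notebook load P={self.p} is high for M={self.m}; "
                          "retrieval fidelity may degrade", stacklevel=2)
        return self

    # -- retrieval dynamics ----------------------------------------------
    def _kwta(self, h: np.ndarray) -> np.ndarray:
        """Exactly-k winners-take-all per column of h (M × B)."""
        h = h + self._tie[:, None]
        part = np.argpartition(-h, self.k - 1, axis=0)[: self.k]
        s = np.zeros(h.shape, dtype=np.uint8)
        np.put_along_axis(s, part, 1, axis=0)
        return s

    def complete(self, init: np.ndarray, cycles: int = 9) -> np.ndarray:
        """Run synchronous retrieval from binary state(s) ``init``.

        ``init`` is (M,) or (M, B); each cycle computes the recurrent input and
        applies k-WTA.  Stops early if every state is already a fixed point.
        """
        init = np.asarray(init)
        single = init.ndim == 1
        s = init.astype(np.float64)[:, None] if single else init.astype(np.float64)
        for _ in range(cycles):
            new = self._kwta(self.w_rec @ s).astype(np.float64)
            if np.array_equal(new, s):
                s = new
                break
            s = new
        return s[:, 0].astype(np.uint8) if single else s.astype(np.uint8)

    def is_fixed_point(self, state: np.ndarray) -> bool:
        return np.array_equal(self.complete(state, cycles=1), state.astype(np.uint8))

    def fixed_point_fraction(self) -> float:
        """Fraction of stored indices invariant under one retrieval cycle."""
        out = self.complete(self.indices.T.astype(np.float64), cycles=1)
        return float(np.mean(np.all(out == self.indices.T, axis=0)))

    # -- readout ----------------------------------------------------------
    def _readout(self, states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        scale = 1.0 / (self.a * self.m * (1.0 - self.a))
        sf = states.astype(np.float64)
        return self.w_ns_x @ sf * scale, self.w_ns_y @ sf * scale

    def sample_reactivations(self, count: int, seed: int = 0, *,
                             return_states: bool = False):
        """Offline replay: random sparse initial states settle into attractors,
        which are read out as reactivated (x̃, ỹ) pairs."""
        if self.p < 1:
            raise ValueError("notebook is empty")
        rng = child_rng(seed, "reactivation-init")
        init = self._draw_indices(count, rng).T.astype(np.float64)
        states = self.complete(init)
        x, y = self._readout(states)
        if return_states:
            return x, y, states
        return x, y

    def cued_recall(self, x_cue: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Student in → notebook → student out.

        The cue is projected through the student→notebook weights, sparsified
        by k-WTA, pattern-completed, and both student layers are read out.
        Only input-layer weights drive the cue (the output is unknown at query
        time).
        """
        if self.p < 1:
            raise ValueError("notebook is empty")
        cue = np.asarray(x_cue, dtype=float)
        single = cue.ndim == 1
        if single:
            cue = cue[:, None]
        init = self._kwta(self.w_sn @ cue).astype(np.float64)
        states = self.complete(init)
        x, y = self._readout(states)
        if single:
            return x[:, 0], float(y[0])
        return x, y

    def errors(self, train: ExampleSet, teacher: TeacherSpec, p_test: int = 1000,
               seed: int = 0) -> tuple[float, float]:
        """(memorization error, generalization error) of the notebook pathway.

        Memorization: cued recall on the stored inputs scored against the
        stored outputs.  Generalization: cued recall on fresh teacher
        examples — effectively nearest-neighbor regression, so it is bounded
        below by σ_ε² and suffers the curse of dimensionality.
        """
        _, y_mem = self.cued_recall(train.inputs)
        mem = float(np.mean((train.outputs - y_mem) ** 2))
        test = sample_examples(teacher, p_test, seed=child_seed(seed, "nb-test"))
        _, y_gen = self.cued_recall(test.inputs)
        gen = float(np.mean((test.outputs - y_gen) ** 2))
        return mem, gen


# -- functional wrappers --------------------------------------------------

def encode(notebook: Notebook, data: ExampleSet, seed: int | None = None) -> Notebook:
    return notebook.encode(data, seed=seed)


def complete(notebook: Notebook, init_index: np.ndarray, cycles: int = 9) -> np.ndarray:
    return notebook.complete(init_index, cycles=cycles)


def sample_reactivations(notebook: Notebook, count: int, seed: int = 0):
    return notebook.sample_reactivations(count, seed=seed)


def cued_recall(notebook: Notebook, x_cue: np.ndarray):
    return notebook.cued_recall(x_cue)


def notebook_errors(notebook: Notebook, train: ExampleSet, teacher: TeacherSpec,
                    p_test: int = 1000, seed: int = 0) -> tuple[float, float]:
    return notebook.errors(train, teacher, p_test=p_test, seed=seed)


def nearest_neighbor_errors(train: ExampleSet, teacher: TeacherSpec,
                            p_test: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Brute-force 1-nearest-neighbor regression on the stored set.

    The idealized limit of the notebook pathway: each query returns the output
    of the closest (Euclidean) stored input.  Used as the notebook-only system
    in large sweeps and as an independent oracle for the Hopfield pathway.
    """
    def _predict(queries: np.ndarray) -> np.ndarray:
        # ||q - x||^2 = ||q||^2 - 2 q.x + ||x||^2; argmin over stored x
        cross = train.inputs.T @ queries                      # (P, B)
        norms = np.sum(train.inputs**2, axis=0)[:, None]
        idx = np.argmax(2 * cross - norms, axis=0)
        return train.outputs[idx]

    mem = float(np.mean((train.outputs - _predict(train.inputs)) ** 2))
    test = sample_examples(teacher, p_test, seed=child_seed(seed, "nb-test"))
    gen = float(np.mean((test.outputs - _predict(test.inputs)) ** 2))
    return mem, gen


# -- serialization --------------------------------------------------------

def save_notebook(nb: Notebook, outdir: str | Path) -> None:
    """Binary-free bundle: JSON metadata + CSV matrices (exact round-trip)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"m": nb.m, "sparsity": nb.a, "n_inputs": nb.n_inputs, "seed": nb.seed}
    (outdir / "meta.json").write_text(json.dumps(meta))
    np.savetxt(outdir / "indices.csv", nb.indices, fmt="%d", delimiter=",")
    for name in ("w_rec", "w_sn", "w_ns_x"):
        np.savetxt(outdir / f"{name}.csv", getattr(nb, name), fmt="%.17g", delimiter=",")
    np.savetxt(outdir / "w_ns_y.csv", nb.w_ns_y, fmt="%.17g", delimiter=",")
    np.savetxt(outdir / "stored_x.csv", nb._stored_x, fmt="%.17g", delimiter=",")
    np.savetxt(outdir / "stored_y.csv", nb._stored_y, fmt="%.17g", delimiter=",")


def load_notebook(outdir: str | Path) -> Notebook:
    outdir = Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    nb = Notebook(meta["m"], meta["sparsity"], meta["n_inputs"], meta["seed"])
    nb.indices = np.loadtxt(outdir / "indices.csv", delimiter=",", ndmin=2).astype(np.uint8)
    for name in ("w_rec", "w_sn", "w_ns_x"):
        setattr(nb, name, np.loadtxt(outdir / f"{name}.csv", delimiter=",", ndmin=2))
    nb.w_ns_y = np.loadtxt(outdir / "w_ns_y.csv", delimiter=",")
    nb._stored_x = np.loadtxt(outdir / "stored_x.csv", delimiter=",", ndmin=2)
    nb._stored_y = np.atleast_1d(np.loadtxt(outdir / "stored_y.csv", delimiter=","))
    return nb
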