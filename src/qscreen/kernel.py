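"""Quantum-inspired kernels and the statevector simulation oracle.

The screening kernel encodes, for every selected feature, the difference
between two participants' (standardized, importance-scaled) values as the
angle of a single-qubit Y rotation applied to |0>.  Measuring the
probability of remaining in |0> gives the per-feature overlap
cos^2(delta/2); the kernel aggregates these overlaps through a softmax-
importance-weighted sum.  Because each feature lives on its own qubit and
no entangling gate is used, the kernel factorizes and is computed here in
closed form, with a small exact statevector simulator serving as an
independent oracle (and powering the Z / ZZ feature-map benchmark
kernels, which do build full product/entangled circuits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SQRT2 = np.sqrt(2.0)

# -- gate matrices -----------------------------------------------------------

H_GATE = np.array([[1, 1], [1, -1]], dtype=complex) / SQRT2
X_GATE = np.array([[0, 1], [1, 0]], dtype=complex)
SX_GATE = 0.5 * np.array([[1 + 1j, 1 - 1j], [1 - 1j, 1 + 1j]], dtype=complex)


def rx(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -1j * s], [-1j * s, c]], dtype=complex)


def ry(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def rz(theta: float) -> np.ndarray:
    return np.array([[np.exp(-1j * theta / 2), 0],
                     [0, np.exp(1j * theta / 2)]], dtype=complex)


def p_gate(phi: float) -> np.ndarray:
    """Phase gate diag(1, e^{i phi})."""
    return np.array([[1, 0], [0, np.exp(1j * phi)]], dtype=complex)


_FIXED_GATES = {"H": H_GATE, "X": X_GATE, "SX": SX_GATE}
_PARAM_GATES = {"RX": rx, "RY": ry, "RZ": rz, "P": p_gate}


@dataclass
class SingleQubitGate:
    """A named 2x2 unitary, optionally parameterized by an angle."""

    name: str
    angle: float | None = None
    matrix: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.name in _FIXED_GATES:
            self.matrix = _FIXED_GATES[self.name]
        elif self.name in _PARAM_GATES:
            if self.angle is None:
                raise ValueError(f"{self.name} needs an angle")
            self.matrix = _PARAM_GATES[self.name](self.angle)
        else:
            raise ValueError(f"unknown gate {self.name!r}")
        ident = self.matrix @ self.matrix.conj().T
        if not np.allclose(ident, np.eye(2), atol=1e-12):
            raise ValueError(f"{self.name} matrix not unitary")


@dataclass
class QuantumCircuit:
    """Ordered list of (gate, target, optional control) on n qubits.

    Qubit 0 is the most significant bit of the computational-basis index,
    so a state on qubits (q0, q1) indexes as |q0 q1>.
    """

    n_qubits: int
    gates: list[tuple[SingleQubitGate, int, int | None]] = field(
        default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.n_qubits <= 20):
            raise ValueError("n_qubits must be in [1, 20]")

    def add(self, gate: SingleQubitGate, target: int,
            control: int | None = None) -> "QuantumCircuit":
        for q in (target,) if control is None else (target, control):
            if not (0 <= q < self.n_qubits):
                raise ValueError(f"qubit index {q} out of range")
        if control == target:
            raise ValueError("control equals target")
        self.gates.append((gate, target, control))
        return self

    def to_json_records(self) -> list[dict]:
        return [
            {"gate": g.name, "angle": g.angle, "target": t, "control": c}
            for g, t, c in self.gates
        ]


def _apply_1q(state: np.ndarray, mat: np.ndarray, target: int,
              n: int) -> np.ndarray:
    psi = state.reshape([2] * n)
    psi = np.moveaxis(psi, target, 0)
    psi = np.tensordot(mat, psi, axes=([1], [0]))
    psi = np.moveaxis(psi, 0, target)
    return psi.reshape(-1)


def _apply_controlled(state: np.ndarray, mat: np.ndarray, target: int,
                      control: int, n: int) -> np.ndarray:
    psi = state.reshape([2] * n).copy()
    psi = np.moveaxis(psi, (control, target), (0, 1))
    psi[1] = np.tensordot(mat, psi[1], axes=([1], [0]))
    psi = np.moveaxis(psi, (0, 1), (control, target))
    return psi.reshape(-1)


def statevector_simulate(circuit: QuantumCircuit,
                         initial_state: np.ndarray | None = None
                         ) -> np.ndarray:
    """Exact amplitudes of the circuit applied to |0...0> (or a given state)."""
    n = circuit.n_qubits
    if initial_state is None:
        state = np.zeros(2 ** n, dtype=complex)
        state[0] = 1.0
    else:
        state = np.asarray(initial_state, dtype=complex).copy()
        if state.shape != (2 ** n,):
            raise ValueError("initial state has wrong dimension")
    for gate, target, control in circuit.gates:
        if control is None:
            state = _apply_1q(state, gate.matrix, target, n)
        else:
            state = _apply_controlled(state, gate.matrix, target, control, n)
    return state


# ---------------------------------------------------------------------------
# The screening kernel
# ---------------------------------------------------------------------------

def feature_overlap(delta: float) -> float:
    """P(|0>) after R_Y(delta) on |0>: cos^2(delta/2).

    Equal inputs give delta = 0 and overlap 1; a pi difference rotates the
    qubit to |1> and gives overlap 0.
    """
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return float(np.cos(delta / 2.0) ** 2)


def feature_overlap_expectation_z(delta: float) -> float:
    """Alternative measurement semantics: <Z> = cos(delta) after R_Y(delta)."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return float(np.cos(delta))


def kernel_value(a: np.ndarray, b: np.ndarray, weights: np.ndarray,
                 semantics: str = "p0") -> float:
    """Softmax-importance-weighted sum of per-feature qubit overlaps.

    K(a, b) = sum_i w_i cos^2((a_i - b_i) / 2), with w_i > 0 summing to 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.shape != b.shape or a.shape != w.shape:
        raise ValueError("a, b, weights must have equal lengths")
    delta = a - b
    if semantics == "p0":
        per_qubit = np.cos(delta / 2.0) ** 2
    elif semantics == "expectation_z":
        per_qubit = np.cos(delta)
    else:
        raise ValueError(f"unknown semantics {semantics!r}")
    return float(np.sum(w * per_qubit))


@dataclass
class GramMatrix:
    """Pairwise kernel values with row/column identifiers."""

    values: np.ndarray
    row_ids: list
    col_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("Gram shape does not match ids")

    @property
    def is_square(self) -> bool:
        return self.row_ids == self.col_ids

    def validate_train(self, eig_tol: float = -1e-8) -> None:
        """Square train Gram must be symmetric, unit-diagonal and PSD."""
        K = self.values
        if K.shape[0] != K.shape[1]:
            raise ValueError("train Gram must be square")
        if np.max(np.abs(K - K.T)) > 1e-10:
            raise ValueError("train Gram not symmetric")
        if np.max(np.abs(np.diag(K) - 1.0)) > 1e-10:
            raise ValueError("train Gram diagonal not 1")
        min_eig = float(np.linalg.eigvalsh((K + K.T) / 2).min())
        if min_eig < eig_tol:
            raise ValueError(f"train Gram not PSD (min eig {min_eig:g})")


def gram_matrix(A: np.ndarray, B: np.ndarray, weights: np.ndarray,
                row_ids: list | None = None, col_ids: list | None = None,
                semantics: str = "p0") -> GramMatrix:
    """Pairwise kernel_value over the rows of A and B (vectorized)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    w = np.asarray(weights, dtype=float)
    if A.shape[1] != B.shape[1] or A.shape[1] != len(w):
        raise ValueError("feature dimensions do not match the weights")
    delta = A[:, None, :] - B[None, :, :]
    if semantics == "p0":
        per_qubit = np.cos(delta / 2.0) ** 2
    elif semantics == "expectation_z":
        per_qubit = np.cos(delta)
    else:
        raise ValueError(f"unknown semantics {semantics!r}")
    K = per_qubit @ w
    if row_ids is None:
        row_ids = list(range(A.shape[0]))
    if col_ids is None:
        col_ids = list(range(B.shape[0]))
    return GramMatrix(K, list(row_ids), list(col_ids))


def kernel_value_statevector(a, b, weights) -> float:
    """Oracle: per-qubit R_Y(a_i) R_Y(-b_i) simulation + weighted P(|0>)."""
    total = 0.0
    for ai, bi, wi in zip(a, b, weights):
        circ = QuantumCircuit(1)
        circ.add(SingleQubitGate("RY", ai), 0)
        circ.add(SingleQubitGate("RY", -bi), 0)
        amp = statevector_simulate(circ)
        total += wi * float(np.abs(amp[0]) ** 2)
    return total


def sample_kernel_value(a, b, weights, shots: int, rng) -> float:
    """Shot-sampled kernel: binomial measurement noise per qubit (off by
    default everywhere; provided for studying finite-shot behavior)."""
    total = 0.0
    for ai, bi, wi in zip(a, b, weights):
        p = feature_overlap(ai - bi)
        total += wi * rng.binomial(shots, min(max(p, 0.0), 1.0)) / shots
    return total


# ---------------------------------------------------------------------------
# R_Y decomposition diagnostic
# ---------------------------------------------------------------------------

def verify_ry_decomposition(theta: float) -> dict:
    """Compare measurement outcomes of R_Y(theta) against two gate sequences.

    * the commonly printed sequence RZ(-pi/2), SX, RZ(theta), SX, RZ(-pi/2)
      (circuit order), whose P(|0>) works out to sin^2(theta/2) — the
      complement of the R_Y outcome, so a diagnostic flag is raised when
      they disagree;
    * the canonical ZSX decomposition RZ(pi) -> SX -> RZ(pi - theta) -> SX
      (circuit order), which equals R_Y(theta) up to a global phase.
    """
    ry_mat = ry(theta)
    p0_exact = float(np.abs(ry_mat[0, 0]) ** 2)

    # circuit order g1..gn => matrix product gn ... g1
    printed = rz(-np.pi / 2) @ SX_GATE @ rz(theta) @ SX_GATE @ rz(-np.pi / 2)
    p0_printed = float(np.abs(printed[0, 0]) ** 2)

    canonical = SX_GATE @ rz(np.pi - theta) @ SX_GATE @ rz(np.pi)
    # strip global phase before comparing
    k = np.argmax(np.abs(canonical))
    idx = np.unravel_index(k, canonical.shape)
    phase = canonical[idx] / ry_mat[idx] if abs(ry_mat[idx]) > 1e-12 else 1.0
    max_dev = float(np.max(np.abs(canonical / phase - ry_mat)))

    return {
        "theta": float(theta),
        "p0_exact_ry": p0_exact,
        "p0_printed_sequence": p0_printed,
        "printed_matches_ry": bool(abs(p0_printed - p0_exact) < 1e-12),
        "printed_is_complement": bool(
            abs(p0_printed - np.sin(theta / 2.0) ** 2) < 1e-12),
        "canonical_max_deviation": max_dev,
        "diagnostic_flag": bool(abs(p0_printed - p0_exact) >= 1e-12),
    }


# ---------------------------------------------------------------------------
# Benchmark feature-map kernels
# ---------------------------------------------------------------------------

def _z_map_state_1q(x: float, reps: int) -> np.ndarray:
    state = np.array([1.0, 0.0], dtype=complex)
    for _ in range(reps):
        state = H_GATE @ state
        state = p_gate(2.0 * x) @ state
    return state


def z_featuremap_kernel(a, b, reps: int = 2) -> float:
    """Fidelity kernel of the (entanglement-free) Z feature map.

    Each feature's qubit runs H then P(2x), ``reps`` times; the product
    structure lets the fidelity factorize over qubits.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fid = 1.0
    for ai, bi in zip(a, b):
        sa = _z_map_state_1q(ai, reps)
        sb = _z_map_state_1q(bi, reps)
        fid *= float(np.abs(np.vdot(sa, sb)) ** 2)
    return fid


def _zz_map_circuit(x: np.ndarray, reps: int) -> QuantumCircuit:
    n = len(x)
    circ = QuantumCircuit(n)
    for _ in range(reps):
        for q in range(n):
            circ.add(SingleQubitGate("H"), q)
            circ.add(SingleQubitGate("P", 2.0 * x[q]), q)
        for q in range(n - 1):  # linear-chain pairing
            phi = 2.0 * (np.pi - x[q]) * (np.pi - x[q + 1])
            circ.add(SingleQubitGate("X"), q + 1, control=q)
            circ.add(SingleQubitGate("P", phi), q + 1)
            circ.add(SingleQubitGate("X"), q + 1, control=q)
    return circ


def zz_featuremap_state(x, reps: int = 2) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if len(x) > 20:
        raise ValueError(
            "ZZ feature map limited to 20 features; pass a feature subset")
    return statevector_simulate(_zz_map_circuit(x, reps))


def zz_featuremap_kernel(a, b, reps: int = 2) -> float:
    """Fidelity kernel of the entangling ZZ feature map (linear chain)."""
    sa = zz_featuremap_state(a, reps)
    sb = zz_featuremap_state(b, reps)
    return float(np.abs(np.vdot(sa, sb)) ** 2)


def featuremap_gram(X: np.ndarray, Y: np.ndarray, kind: str = "z",
                    reps: int = 2) -> np.ndarray:
    """Gram matrix under the Z or ZZ feature-map fidelity kernel.

    States are prepared once per distinct row, then paired, so the cost is
    linear in samples for the state preparation.
    """
    X = np.atleast_2d(X)
    Y = np.atleast_2d(Y)
    if kind == "z":
        def state(x):
            per_q = [_z_map_state_1q(v, reps) for v in x]
            out = per_q[0]
            for s in per_q[1:]:
                out = np.kron(out, s)
            return out
    elif kind == "zz":
        def state(x):
            return zz_featuremap_state(x, reps)
    else:
        raise ValueError(f"unknown feature map {kind!r}")
    states_x = np.array([state(x) for x in X])
    states_y = (states_x if (Y is X or (X.shape == Y.shape and
                                        np.array_equal(X, Y)))
                else np.array([state(y) for y in Y]))
    overlaps = states_x.conj() @ states_y.T
    return np.abs(overlaps) ** 2
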