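"""Constant-weight binary spatial patterns and spatiotemporal context sequences.

Input frames are binary vectors of length ``n`` with a fixed number of active
("1") elements; a pattern set holds ``k`` such frames with an *exact* pairwise
Hamming distance between every pair.  Sequences stack ``t_len`` frames and
carry a context label: a *same*-context sequence repeats one frame, a
*different*-context sequence mixes frames from the set.

The exact-distance construction is a shared-core design: all patterns agree on
a random core of ``ones_count - hd/2`` active positions and each pattern adds
its own disjoint block of ``hd/2`` unique active positions, which forces every
pairwise distance to exactly ``hd``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

__all__ = [
    "PatternSet",
    "InputSequence",
    "generate_pattern_set",
    "make_same_context_sequence",
    "make_different_context_sequence",
    "hamming_distance",
    "cosine_similarity",
    "save_pattern_set",
    "load_pattern_set",
    "save_sequence",
    "load_sequence",
]

Context = Literal["same", "different"]


def _as_binary_vector(x, name: str = "pattern") -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(np.uint8)


def _as_binary_matrix(x, name: str = "patterns") -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 2:
        raise ValueError(f"{name} must be two-dimensional, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(np.uint8)


def hamming_distance(a, b) -> int:
    """Number of positions at which two equal-length binary vectors differ."""
    a = _as_binary_vector(a, "a")
    b = _as_binary_vector(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int(np.count_nonzero(a != b))


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors, ``dot(a, b) / (|a| |b|)``.

    For two constant-weight binary vectors with ``m`` ones each and overlap
    ``v`` this equals ``v / m``; with the defaults used here (60 ones,
    Hamming distance 10, hence overlap 55) it is 55/60 ≈ 0.9167.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm input")
    return float(a @ b / (na * nb))


@dataclass(frozen=True)
class PatternSet:
    """Ordered set of constant-weight binary spatial patterns.

    Parameters
    ----------
    matrix : (k, n) array of 0/1
        One pattern per row.
    hd : int or None
        Exact pairwise Hamming distance the set was built with; ``None`` when
        unconstrained (single pattern).
    seed : int or None
        Seed used by the generator, recorded for provenance.
    """

    matrix: np.ndarray
    hd: int | None = None
    seed: int | None = None

    def __post_init__(self):
        m = _as_binary_matrix(self.matrix)
        object.__setattr__(self, "matrix", m)
        ones = m.sum(axis=1)
        if len(ones) and not (ones == ones[0]).all():
            raise ValueError("all patterns must have the same number of ones")
        if self.hd is not None:
            for i in range(len(m)):
                for j in range(i + 1, len(m)):
                    d = int(np.count_nonzero(m[i] != m[j]))
                    if d != self.hd:
                        raise ValueError(
                            f"patterns {i},{j} have Hamming distance {d}, expected {self.hd}"
                        )

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def ones_count(self) -> int:
        return int(self.matrix[0].sum()) if self.k else 0

    @property
    def patterns(self) -> list[np.ndarray]:
        return [self.matrix[i] for i in range(self.k)]

    def __len__(self) -> int:
        return self.k

    def __getitem__(self, i: int) -> np.ndarray:
        return self.matrix[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.patterns)


@dataclass(frozen=True)
class InputSequence:
    """Ordered stack of input frames with a context label."""

    frames: np.ndarray  # (t_len, n)
    context: Context
    seed: int | None = None

    def __post_init__(self):
        f = _as_binary_matrix(self.frames, "frames")
        object.__setattr__(self, "frames", f)
        if self.context not in ("same", "different"):
            raise ValueError(f"context must be 'same' or 'different', got {self.context!r}")
        if self.context == "same" and len(f) > 1 and not (f == f[0]).all():
            raise ValueError("same-context sequence must repeat a single frame")

    @property
    def t_len(self) -> int:
        return self.frames.shape[0]

    @property
    def n(self) -> int:
        return self.frames.shape[1]


def generate_pattern_set(
    n: int = 120,
    k: int = 5,
    hd: int = 10,
    ones_count: int | None = None,
    seed: int | None = None,
) -> PatternSet:
    """Generate ``k`` random binary patterns of length ``n`` with ``ones_count``
    ones each and *exact* pairwise Hamming distance ``hd``.

    Uses the shared-core construction: a common random core of
    ``c = ones_count - hd/2`` active positions plus ``k`` disjoint random
    blocks of ``hd/2`` unique active positions.  Two patterns then differ in
    exactly their two unique blocks, i.e. in ``hd`` positions.

    Raises
    ------
    ValueError
        If the combination is infeasible (``hd`` odd, ``c < 0`` or
        ``c + k*hd/2 > n``) or parameters are out of range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    if ones_count is None:
        if n % 2 != 0:
            raise ValueError("default ones_count = n/2 requires even n")
        ones_count = n // 2
    if not 0 <= ones_count <= n:
        raise ValueError(f"ones_count must be in [0, {n}], got {ones_count}")

    rng = np.random.default_rng(seed)

    if k == 1:
        bits = np.zeros(n, dtype=np.uint8)
        bits[rng.permutation(n)[:ones_count]] = 1
        return PatternSet(bits[None, :], hd=None, seed=seed)

    if hd <= 0 or hd % 2 != 0:
        raise ValueError(f"pairwise Hamming distance must be positive and even, got {hd}")
    half = hd // 2
    core_size = ones_count - half
    if core_size < 0:
        raise ValueError(
            f"infeasible: ones_count={ones_count} < hd/2={half} (shared core would be negative)"
        )
    if core_size + k * half > n:
        raise ValueError(
            f"infeasible: core ({core_size}) + {k} disjoint blocks of {half} exceeds n={n}"
        )

    perm = rng.permutation(n)
    core = perm[:core_size]
    blocks = perm[core_size : core_size + k * half].reshape(k, half)

    matrix = np.zeros((k, n), dtype=np.uint8)
    matrix[:, core] = 1
    for i in range(k):
        matrix[i, blocks[i]] = 1
    return PatternSet(matrix, hd=hd, seed=seed)


def make_same_context_sequence(pattern, t_len: int = 5) -> InputSequence:
    """Repeat one spatial pattern for ``t_len`` frames (same-context input)."""
    if t_len < 1:
        raise ValueError("t_len must be >= 1")
    p = _as_binary_vector(pattern)
    return InputSequence(np.tile(p, (t_len, 1)), context="same")


def make_different_context_sequence(
    ps: PatternSet,
    mode: Literal["canonical", "randomized"] = "canonical",
    t_len: int = 5,
    seed: int | None = None,
    replace: bool = False,
) -> InputSequence:
    """Build a different-context sequence from a pattern set.

    ``canonical`` emits the patterns in order (A_1, …, A_k) — the standard
    training condition — and requires ``t_len == k``.  ``randomized`` draws
    the first ``t_len - 1`` frames from the set (without replacement by
    default) and keeps the last pattern as the final frame.
    """
    if mode == "canonical":
        if t_len != ps.k:
            raise ValueError(f"canonical mode requires t_len == k ({ps.k}), got {t_len}")
        return InputSequence(ps.matrix.copy(), context="different", seed=seed)
    if mode != "randomized":
        raise ValueError(f"mode must be 'canonical' or 'randomized', got {mode!r}")
    if t_len < 1:
        raise ValueError("t_len must be >= 1")
    n_random = t_len - 1
    if not replace and n_random > ps.k:
        raise ValueError(
            f"cannot draw {n_random} distinct frames from {ps.k} patterns without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(ps.k, size=n_random, replace=replace)
    frames = np.vstack([ps.matrix[idx], ps.matrix[-1][None, :]])
    return InputSequence(frames, context="different", seed=seed)


# -- plain-text serialization (one row per pattern/frame, space-separated 0/1,
#    JSON sidecar with provenance) ------------------------------------------


def _write_matrix(path: Path, matrix: np.ndarray, meta: dict) -> None:
    np.savetxt(path, matrix, fmt="%d")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def _read_matrix(path: Path) -> tuple[np.ndarray, dict]:
    matrix = np.atleast_2d(np.loadtxt(path, dtype=np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return matrix, meta


def save_pattern_set(path, ps: PatternSet) -> None:
    _write_matrix(Path(path), ps.matrix, {"kind": "pattern_set", "hd": ps.hd, "seed": ps.seed})


def load_pattern_set(path) -> PatternSet:
    matrix, meta = _read_matrix(Path(path))
    return PatternSet(matrix, hd=meta.get("hd"), seed=meta.get("seed"))


def save_sequence(path, seq: InputSequence) -> None:
    _write_matrix(
        Path(path), seq.frames, {"kind": "sequence", "context": seq.context, "seed": seq.seed}
    )


def load_sequence(path) -> InputSequence:
    frames, meta = _read_matrix(Path(path))
    return InputSequence(frames, context=meta.get("context", "different"), seed=meta.get("seed"))
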