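"""Reversible amino-acid substitution models.

A model is parameterised by equilibrium frequencies ``pi`` and a symmetric
exchangeability matrix ``s``; the generator has off-diagonal rates
``q_ij = s_ij * pi_j`` and is rescaled at build time so that the expected
number of substitutions per unit time at stationarity equals one
(``-sum_i pi_i q_ii = 1``), the convention that makes branch lengths read as
substitutions per site.  Reversibility (detailed balance
``pi_i q_ij = pi_j q_ji``) follows from the construction.

Transition probabilities ``P(t) = exp(Qt)`` are computed through the
symmetric eigendecomposition of ``diag(sqrt(pi)) Q diag(1/sqrt(pi))``, which
is numerically exact for reversible generators and also drives the closed
form expected-count integrals used by the EM machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import path_or_text as _path_or_text
from .alphabet import AMINO, Alphabet

__all__ = [
    "ReversibleModel",
    "ClassPartition",
    "ClassRateSummary",
    "build_model",
    "jukes_cantor_like",
    "transition_probabilities",
    "class_rate_statistics",
    "read_paml_matrix",
    "write_paml_matrix",
]


@dataclass(frozen=True)
class ReversibleModel:
    """A reversible substitution model with unit mean rate at stationarity."""

    pi: np.ndarray
    s: np.ndarray
    Q: np.ndarray
    name: str = ""
    alphabet: Alphabet = AMINO
    _eig: tuple = field(init=False, repr=False, compare=False, default=None)

    @property
    def size(self) -> int:
        return self.pi.shape[0]

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigenvalues ``w`` and matrices ``U``, ``Uinv`` with Q = U diag(w) Uinv.

        Computed once through the similar symmetric matrix
        ``B = diag(sqrt(pi)) Q diag(1/sqrt(pi))`` and cached.
        """
        if self._eig is None:
            sp = np.sqrt(self.pi)
            B = (sp[:, None] * self.Q) / sp[None, :]
            B = 0.5 * (B + B.T)  # symmetrize rounding noise
            w, R = np.linalg.eigh(B)
            U = R / sp[:, None]
            Uinv = R.T * sp[None, :]
            object.__setattr__(self, "_eig", (w, U, Uinv))
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_probabilities(self, t)


def build_model(
    pi: np.ndarray,
    s: np.ndarray,
    name: str = "",
    alphabet: Alphabet = AMINO,
) -> ReversibleModel:
    """Assemble a normalized reversible model from frequencies and exchangeabilities.

    Parameters
    ----------
    pi : array of shape (n,)
        Equilibrium frequencies; strictly positive, summing to 1 (renormalized
        when within 1e-8 of 1).
    s : array of shape (n, n)
        Symmetric nonnegative exchangeabilities with zero diagonal.  The scale
        of ``s`` is immaterial: generator and exchangeabilities are rescaled
        jointly so that ``-sum_i pi_i Q_ii = 1``.
    """
    pi = np.asarray(pi, dtype=float).copy()
    s = np.asarray(s, dtype=float).copy()
    n = pi.shape[0]
    if s.shape != (n, n):
        raise ValueError(f"exchangeability shape {s.shape} != ({n}, {n})")
    if alphabet.size != n:
        raise ValueError("alphabet size does not match frequency vector")
    if np.any(pi <= 0):
        raise ValueError("frequencies must be strictly positive (apply a floor first)")
    total = pi.sum()
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"frequencies sum to {total}, not 1")
    pi /= total
    if np.any(s < 0):
        raise ValueError("negative exchangeability")
    if not np.allclose(s, s.T, atol=0, rtol=0):
        raise ValueError("exchangeability matrix must be exactly symmetric")
    if np.any(np.diag(s) != 0):
        raise ValueError("exchangeability diagonal must be zero")
    if not np.any(s > 0):
        raise ValueError("all exchangeabilities are zero: degenerate process")

    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(np.dot(pi, np.diag(Q)))
    if scale <= 0:
        raise ValueError("degenerate generator (zero mean rate)")
    Q /= scale
    s = s / scale
    return ReversibleModel(pi=pi, s=s, Q=Q, name=name, alphabet=alphabet)


def jukes_cantor_like(alphabet: Alphabet = AMINO, name: str = "JC") -> ReversibleModel:
    """The symmetric n-state analogue of Jukes-Cantor: uniform pi, equal s."""
    n = alphabet.size
    pi = np.full(n, 1.0 / n)
    s = np.ones((n, n))
    np.fill_diagonal(s, 0.0)
    return build_model(pi, s, name=name, alphabet=alphabet)


def transition_probabilities(model: ReversibleModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via the cached symmetric eigendecomposition.

    Entries in [-1e-12, 0) from rounding are clipped to 0; rows sum to 1
    to within 1e-10.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    w, U, Uinv = model.eigensystem()
    P = (U * np.exp(w * t)[None, :]) @ Uinv
    np.clip(P, 0.0, None, out=P)
    return P


# ---------------------------------------------------------------------------
# order/disorder residue classes


#: Residues enriched in structured regions (large hydrophobic, aromatic, C).
DEFAULT_ORDER_SET = ("I", "L", "V", "W", "Y", "F", "C")
#: Residues enriched in intrinsically disordered regions.
DEFAULT_DISORDER_SET = ("R", "K", "E", "Q", "A", "G", "S", "P")


@dataclass(frozen=True)
class ClassPartition:
    """Disjoint order-promoting / disorder-promoting residue classes.

    Residues in neither class are 'neutral'.  The default follows the common
    biophysical classification (order: I L V W Y F C; disorder: R K E Q A G S
    P) and is user-configurable via JSON sidecars.
    """

    order_set: tuple[str, ...] = DEFAULT_ORDER_SET
    disorder_set: tuple[str, ...] = DEFAULT_DISORDER_SET
    alphabet: Alphabet = AMINO

    def __post_init__(self) -> None:
        o, d = set(self.order_set), set(self.disorder_set)
        if not o or not d:
            raise ValueError("order and disorder classes must be nonempty")
        if o & d:
            raise ValueError(f"classes overlap: {sorted(o & d)}")
        unknown = (o | d) - set(self.alphabet.residues)
        if unknown:
            raise ValueError(f"residues outside alphabet: {sorted(unknown)}")

    @property
    def neutral_set(self) -> tuple[str, ...]:
        used = set(self.order_set) | set(self.disorder_set)
        return tuple(r for r in self.alphabet.residues if r not in used)

    def indices(self, which: str) -> np.ndarray:
        members = {
            "order": self.order_set,
            "disorder": self.disorder_set,
            "neutral": self.neutral_set,
        }[which]
        return np.array([self.alphabet.index(r) for r in members], dtype=int)

    @classmethod
    def from_json(cls, path_or_text, alphabet: Alphabet = AMINO) -> "ClassPartition":
        obj = json.loads(_path_or_text(path_or_text))
        return cls(
            order_set=tuple(obj["order"]),
            disorder_set=tuple(obj["disorder"]),
            alphabet=alphabet,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"order": list(self.order_set), "disorder": list(self.disorder_set)},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class ClassRateSummary:
    """Substitution flux within and between residue classes.

    ``raw_rates[(A, B)] = sum_{i in A, j in B, i != j} pi_i q_ij`` is the
    stationary substitution flux; ``normalized_rates`` divide by the matching
    frequency mass ``sum_{i in A, j in B, i != j} pi_i pi_j``, i.e. they are
    the frequency-weighted mean exchangeability of the class block.  This
    removes the dependence on source and target composition entirely: under a
    fully exchangeable model every class pair gets the same normalized rate.
    Class keys: 'OO' (within order), 'DD' (within disorder), 'OD' (between).
    """

    raw_rates: dict
    normalized_rates: dict
    ratios: dict


def class_rate_statistics(
    model: ReversibleModel, partition: ClassPartition
) -> ClassRateSummary:
    """Within/between-class substitution rates, raw and frequency-normalized."""
    idx_o = partition.indices("order")
    idx_d = partition.indices("disorder")
    pi, Q = model.pi, model.Q
    Pi_o = float(pi[idx_o].sum())
    Pi_d = float(pi[idx_d].sum())
    if Pi_o <= 0 or Pi_d <= 0:
        raise ValueError("a residue class has total frequency zero")

    flux = pi[:, None] * Q  # off-diagonal: stationary flux i -> j
    mass = pi[:, None] * pi[None, :]

    def block(matrix, rows, cols) -> float:
        sub = matrix[np.ix_(rows, cols)].copy()
        if np.array_equal(rows, cols):
            np.fill_diagonal(sub, 0.0)
        return float(sub.sum())

    raw = {
        "OO": block(flux, idx_o, idx_o),
        "DD": block(flux, idx_d, idx_d),
        "OD": block(flux, idx_o, idx_d) + block(flux, idx_d, idx_o),
    }
    mass_blocks = {
        "OO": block(mass, idx_o, idx_o),
        "DD": block(mass, idx_d, idx_d),
        "OD": block(mass, idx_o, idx_d) + block(mass, idx_d, idx_o),
    }
    # a one-residue class has no within-class pairs: rate undefined (nan)
    norm = {
        key: raw[key] / mass_blocks[key] if mass_blocks[key] > 0 else np.nan
        for key in raw
    }

    def ratio(a, b):
        if np.isnan(norm[a]) or np.isnan(norm[b]):
            return np.nan
        return norm[a] / norm[b] if norm[b] > 0 else np.inf

    ratios = {
        "DD/OD": ratio("DD", "OD"),
        "OO/OD": ratio("OO", "OD"),
        "DD/OO": ratio("DD", "OO"),
    }
    return ClassRateSummary(raw_rates=raw, normalized_rates=norm, ratios=ratios)


# ---------------------------------------------------------------------------
# PAML dat-style matrix files


def write_paml_matrix(model: ReversibleModel, path=None, digits: int = 6) -> str:
    """Serialize a model as a PAML dat-style file.

    Format: n-1 rows of the lower exchangeability triangle (row for residue
    i lists s_{i,0..i-1}), a blank line, then the frequency line, all in the
    canonical residue order.
    """
    if digits < 6:
        raise ValueError("write at least 6 significant digits")
    fmt = f"{{:.{digits}g}}"
    lines = []
    n = model.size
    for i in range(1, n):
        lines.append(" ".join(fmt.format(model.s[i, j]) for j in range(i)))
    lines.append("")
    lines.append(" ".join(fmt.format(p) for p in model.pi))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_paml_matrix(
    path_or_text, alphabet: Alphabet = AMINO, name: str = ""
) -> ReversibleModel:
    """Parse a PAML dat-style lower triangle + frequency line into a model.

    Tolerates blank lines and trailing comments after the frequency line.
    Frequencies not summing to 1 within 1e-3 are rejected; smaller deviations
    are renormalized.
    """
    text = _path_or_text(path_or_text)
    rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            values = [float(tok) for tok in stripped.split()]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric token ({exc})") from None
        rows.append(values)

    n = alphabet.size
    if len(rows) < n:
        raise ValueError(
            f"expected {n - 1} triangle rows plus a frequency line, got {len(rows)} rows"
        )
    tri, freq_row = rows[: n - 1], rows[n - 1]
    s = np.zeros((n, n))
    for i, row in enumerate(tri, start=1):
        if len(row) != i:
            raise ValueError(
                f"triangle row {i} (residue {alphabet.residues[i]}): "
                f"expected {i} values, got {len(row)}"
            )
        for j, v in enumerate(row):
            if v < 0:
                raise ValueError(
                    f"triangle row {i}, column {j + 1}: negative exchangeability {v}"
                )
            s[i, j] = s[j, i] = v
    if len(freq_row) != n:
        raise ValueError(f"frequency line: expected {n} values, got {len(freq_row)}")
    pi = np.array(freq_row, dtype=float)
    if np.any(pi < 0):
        raise ValueError("negative frequency")
    if abs(pi.sum() - 1.0) > 1e-3:
        raise ValueError(f"frequencies sum to {pi.sum():.6f}, outside 1 +- 1e-3")
    pi = pi / pi.sum()
    return build_model(pi, s, name=name, alphabet=alphabet)
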