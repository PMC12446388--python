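"""Reversible amino-acid substitution model and ML pairwise distances.

The model is the standard general time-reversible construction
``Q_ij = S_ij * pi_j`` with the diagonal set for zero row sums and the whole
matrix scaled so the expected substitution rate at stationarity is one.  The
packaged parameterisation is the JTT empirical replacement model; a uniform
"Poisson-style" control model is available for closed-form cross-checks.

Transition probabilities use the symmetrized eigendecomposition of Q, which
is exact and stable for this reversible model class, so ``P(t)`` evaluations
inside the distance optimizer are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ModelError, UndefinedDistanceError, ValidationError
from .io import AMINO_ACIDS, Alignment

N_STATES = 20
T_MAX = 20.0
_OPT_XATOL = 1e-6

# residue -> state index; gap and X map to -1 (excluded from likelihoods)
_STATE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(AMINO_ACIDS):
    _STATE_INDEX[ord(_aa)] = _i


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as state indices, -1 for gap/unknown."""
    return _STATE_INDEX[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SubstitutionModel:
    alphabet: str
    S: np.ndarray
    pi: np.ndarray
    Q: np.ndarray
    # eigendecomposition of diag(sqrt(pi)) Q diag(1/sqrt(pi))
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{-1/2} V
    _right: np.ndarray = field(repr=False, default=None)  # V^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped at 0."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length t must be finite and >= 0, got {t}")
        P = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        return P


def build_model(S: np.ndarray, pi: np.ndarray) -> SubstitutionModel:
    """Assemble a normalized reversible model from exchangeabilities and
    equilibrium frequencies."""
    S = np.asarray(S, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ModelError(f"S must be {N_STATES}x{N_STATES}, got {S.shape}")
    if not np.allclose(S, S.T):
        raise ModelError("exchangeability matrix S must be symmetric")
    if np.any(S < 0):
        raise ModelError("exchangeability matrix S must be non-negative")
    if pi.shape != (N_STATES,):
        raise ModelError(f"pi must have {N_STATES} entries")
    if np.any(pi <= 0):
        raise ModelError("all equilibrium frequencies must be > 0")
    pi = pi / pi.sum()

    Q = S * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    if rate <= 0:
        raise ModelError("degenerate model: expected substitution rate is zero")
    Q = Q / rate

    sqrt_pi = np.sqrt(pi)
    B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    B = (B + B.T) / 2.0  # symmetric up to rounding
    eigvals, V = np.linalg.eigh(B)
    left = V / sqrt_pi[:, None]
    right = V.T * sqrt_pi[None, :]
    return SubstitutionModel(AMINO_ACIDS, S, pi, Q, eigvals, left, right)


def load_jtt(path: str | Path | None = None) -> SubstitutionModel:
    """Load the embedded JTT parameterisation (lower-triangle text file)."""
    if path is None:
        import importlib.resources

        path = importlib.resources.files("domainrates").joinpath("data", "jtt.dat")
    rows = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                rows.append([float(x) for x in line.split()])
    if len(rows) != N_STATES:
        raise ModelError(f"JTT data file must have {N_STATES} numeric rows")
    S = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows[:-1], start=1):
        if len(row) != i:
            raise ModelError(f"triangle row {i + 1} has {len(row)} entries, expected {i}")
        S[i, :i] = row
    S = S + S.T
    pi = np.asarray(rows[-1])
    return build_model(S, pi)


def poisson_model() -> SubstitutionModel:
    """Uniform control model: all exchangeabilities 1, uniform frequencies."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    return build_model(S, np.full(N_STATES, 1.0 / N_STATES))


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# pairwise ML distances
# ---------------------------------------------------------------------------

class MLDistance(NamedTuple):
    t_hat: float
    log_likelihood: float
    n_sites: int
    saturated: bool


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 matrix of joint state counts over columns comparable in both."""
    ok = (a >= 0) & (b >= 0)
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (a[ok], b[ok]), 1.0)
    return counts


def _pair_loglik(counts: np.ndarray, model: SubstitutionModel, t: float) -> float:
    P = model.transition_matrix(t)
    with np.errstate(divide="ignore"):
        logterm = np.log(np.clip(P * model.pi[:, None], 1e-300, None))
    return float(np.sum(counts * logterm))


def pairwise_ml_distance(
    row_a: str,
    row_b: str,
    model: SubstitutionModel,
    t_max: float = T_MAX,
) -> MLDistance:
    """Maximum-likelihood distance between two gapped residue strings.

    Maximizes the joint column likelihood sum(log(pi_a * P_ab(t))) over the
    columns where both rows carry a standard amino acid, by bounded scalar
    optimization on [0, t_max].  Hitting the bound sets the saturated flag.
    """
    if len(row_a) != len(row_b):
        raise ValidationError("sequences must have equal (aligned) lengths")
    a, b = encode(row_a), encode(row_b)
    counts = _pair_counts(a, b)
    n_sites = int(counts.sum())
    if n_sites == 0:
        raise UndefinedDistanceError("no comparable (both non-gap) columns")

    if counts.sum() == np.trace(counts):  # identical over comparable columns
        ll = float(np.sum(np.diag(counts) * np.log(model.pi)))
        return MLDistance(0.0, ll, n_sites, False)

    res = minimize_scalar(
        lambda t: -_pair_loglik(counts, model, t),
        bounds=(1e-9, t_max),
        method="bounded",
        options={"xatol": _OPT_XATOL},
    )
    t_hat = float(res.x)
    saturated = t_hat >= t_max - 10 * _OPT_XATOL
    if saturated:
        t_hat = t_max
    return MLDistance(t_hat, -float(res.fun), n_sites, saturated)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair support counts."""

    def __init__(
        self,
        taxa: list[str],
        values: np.ndarray,
        support: np.ndarray | None = None,
        saturated: np.ndarray | None = None,
    ):
        n = len(taxa)
        values = np.asarray(values, dtype=float)
        if values.shape != (n, n):
            raise ValidationError("distance matrix shape must match taxa")
        if not np.array_equal(values, values.T):
            raise ValidationError("distance matrix must be exactly symmetric")
        if np.any(np.diag(values) != 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(values[np.isfinite(values)] < 0):
            raise ValidationError("distances must be non-negative")
        self.taxa = list(taxa)
        self.values = values
        self.support = (
            np.zeros((n, n), dtype=int) if support is None else np.asarray(support)
        )
        self.saturated = (
            np.zeros((n, n), dtype=bool) if saturated is None else np.asarray(saturated)
        )

    def __len__(self) -> int:
        return len(self.taxa)

    def get(self, taxon_a: str, taxon_b: str) -> float:
        i, j = self.taxa.index(taxon_a), self.taxa.index(taxon_b)
        return float(self.values[i, j])

    def to_phylip(self) -> str:
        lines = [str(len(self.taxa))]
        for name, row in zip(self.taxa, self.values):
            lines.append(name + "  " + " ".join(f"{v:.8f}" for v in row))
        return "\n".join(lines) + "\n"

    def to_long_format(self) -> str:
        lines = ["taxon_a\ttaxon_b\tdistance\tn_sites\tsaturated"]
        for i in range(len(self.taxa)):
            for j in range(i + 1, len(self.taxa)):
                lines.append(
                    f"{self.taxa[i]}\t{self.taxa[j]}\t{self.values[i, j]:.8f}"
                    f"\t{self.support[i, j]}\t{int(self.saturated[i, j])}"
                )
        return "\n".join(lines) + "\n"


def distance_matrix(
    alignment: Alignment,
    model: SubstitutionModel,
    deletion_scheme: str = "complete",
) -> DistanceMatrix:
    """All pairwise ML distances under the given gap-deletion scheme.

    ``complete``: columns with any gap/unknown in any row are removed before
    any comparison (classical complete deletion).  ``pairwise``: each pair
    uses all columns where both members carry a standard amino acid.
    """
    if deletion_scheme not in ("complete", "pairwise"):
        raise ValidationError(f"unknown deletion scheme {deletion_scheme!r}")
    enc = np.array([encode(r.residues) for r in alignment.rows])
    if deletion_scheme == "complete":
        keep = np.all(enc >= 0, axis=0)
        enc = enc[:, keep]
    n = len(alignment.rows)
    values = np.zeros((n, n))
    support = np.zeros((n, n), dtype=int)
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_counts(enc[i], enc[j])
            n_sites = int(counts.sum())
            if n_sites == 0:
                raise UndefinedDistanceError(
                    f"pair ({alignment.rows[i].taxon_id}, "
                    f"{alignment.rows[j].taxon_id}) shares no comparable columns"
                )
            if counts.sum() == np.trace(counts):
                d, sat = 0.0, False
            else:
                res = minimize_scalar(
                    lambda t: -_pair_loglik(counts, model, t),
                    bounds=(1e-9, T_MAX),
                    method="bounded",
                    options={"xatol": _OPT_XATOL},
                )
                d = float(res.x)
                sat = d >= T_MAX - 10 * _OPT_XATOL
                if sat:
                    d = T_MAX
            values[i, j] = values[j, i] = d
            support[i, j] = support[j, i] = n_sites
            saturated[i, j] = saturated[j, i] = sat
    return DistanceMatrix(alignment.taxa, values, support, saturated)
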