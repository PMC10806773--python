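"""Self-avoiding walks on the simple cubic lattice via the pivot algorithm.

The pivot algorithm picks a random internal bead and applies a random
non-identity element of the octahedral symmetry group to one side of the
chain, accepting the move iff the result is self-avoiding.  It is ergodic for
SAWs and decorrelates global observables such as the radius of gyration in
O(1) accepted pivots, which makes it the standard sampler for testing the
Flory scaling Rg ~ N^nu (nu ~= 0.588 in three dimensions).

Chains are stored as integer arrays of shape (n_beads, 3); one lattice unit
corresponds to ``bead_spacing_nm`` (default 0.38 nm, the Calpha-Calpha
distance) when absolute radii are needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = ["ChainEnsemble", "saw_ensemble", "random_walk_ensemble", "walk_rg2",
           "scaling_exponent"]

BEAD_SPACING_NM = 0.38

def _octahedral_matrices() -> np.ndarray:
    """The 48 signed-permutation matrices; identity first."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=np.int64)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            mats.append(m)
    mats.sort(key=lambda m: 0 if np.array_equal(m, np.eye(3, dtype=np.int64)) else 1)
    return np.array(mats)


_MATRICES = _octahedral_matrices()


@dataclass
class ChainEnsemble:
    """A sample of self-avoiding (or ideal) lattice chains of equal length."""

    walks: list[np.ndarray]
    n_beads: int
    seed: int
    bead_spacing_nm: float = BEAD_SPACING_NM

    def __post_init__(self) -> None:
        if self.n_beads < 10:
            raise ValueError("chains must have at least 10 beads")
        for w in self.walks:
            if w.shape != (self.n_beads, 3):
                raise ValueError("all walks must have shape (n_beads, 3)")

    def rg2(self) -> np.ndarray:
        """Per-walk squared radius of gyration, lattice units."""
        return np.array([walk_rg2(w) for w in self.walks])

    def rg_nm(self) -> float:
        """Ensemble root-mean-square Rg in nm."""
        return float(np.sqrt(self.rg2().mean())) * self.bead_spacing_nm


def walk_rg2(walk: np.ndarray) -> float:
    centred = walk - walk.mean(axis=0)
    return float(np.mean(np.sum(centred * centred, axis=1)))


def _pack(coords: np.ndarray, n: int) -> np.ndarray:
    # coordinates of an n-bead walk satisfy |x| <= n, so base 2n+3 is collision-free
    base = np.int64(2 * n + 3)
    shifted = coords.astype(np.int64) + n + 1
    return (shifted[:, 0] * base + shifted[:, 1]) * base + shifted[:, 2]


def _pivot_chain(chain: np.ndarray, n_accept: int, rng: np.random.Generator,
                 max_attempts_factor: int = 10_000) -> np.ndarray:
    """Advance ``chain`` by ``n_accept`` accepted pivot moves (in place copy)."""
    n = chain.shape[0]
    chain = chain.copy()
    accepted = 0
    attempts = 0
    max_attempts = max_attempts_factor * max(n_accept, 1)
    while accepted < n_accept:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - safety valve
            raise RuntimeError("pivot algorithm failed to accept enough moves")
        i = int(rng.integers(1, n - 1))
        m = _MATRICES[int(rng.integers(1, len(_MATRICES)))]
        # transform the shorter side around bead i
        if i < n - 1 - i:
            moving, fixed = chain[:i], chain[i:]
        else:
            moving, fixed = chain[i + 1:], chain[: i + 1]
        new_seg = chain[i] + (moving - chain[i]) @ m.T
        hit = np.isin(
            _pack(new_seg, n), np.sort(_pack(fixed, n)), assume_unique=True, kind="sort"
        )
        if hit.any():
            continue
        moving[:] = new_seg
        accepted += 1
    return chain


def saw_ensemble(n_beads: int, n_walks: int, seed: int,
                 burn_in_factor: int = 10, decorrelation_factor: int = 1) -> ChainEnsemble:
    """Sample ``n_walks`` self-avoiding walks of ``n_beads`` beads.

    One chain is evolved by the pivot algorithm: ``burn_in_factor * n_beads``
    accepted pivots of burn-in from a straight rod, then one sample every
    ``decorrelation_factor * n_beads`` accepted pivots.  Reproducible from
    ``seed``.
    """
    if n_beads < 10:
        raise ValueError("n_beads must be >= 10")
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    rng = np.random.default_rng(seed)
    chain = np.zeros((n_beads, 3), dtype=np.int64)
    chain[:, 0] = np.arange(n_beads)  # straight rod: trivially self-avoiding
    chain = _pivot_chain(chain, burn_in_factor * n_beads, rng)
    walks = []
    for _ in range(n_walks):
        chain = _pivot_chain(chain, decorrelation_factor * n_beads, rng)
        walks.append(chain.copy())
    return ChainEnsemble(walks=walks, n_beads=n_beads, seed=seed)


def random_walk_ensemble(n_beads: int, n_walks: int, seed: int) -> ChainEnsemble:
    """Ideal (non-self-avoiding) simple random walks, for theta-solvent checks."""
    rng = np.random.default_rng(seed)
    walks = []
    for _ in range(n_walks):
        axes = rng.integers(0, 3, size=n_beads - 1)
        signs = rng.choice([-1, 1], size=n_beads - 1)
        steps = np.zeros((n_beads - 1, 3), dtype=np.int64)
        steps[np.arange(n_beads - 1), axes] = signs
        walk = np.zeros((n_beads, 3), dtype=np.int64)
        walk[1:] = np.cumsum(steps, axis=0)
        walks.append(walk)
    return ChainEnsemble(walks=walks, n_beads=n_beads, seed=seed)


def scaling_exponent(ensembles: list[ChainEnsemble]) -> tuple[float, float]:
    """Flory exponent from the log-log slope of <Rg^2> versus chain length.

    Fits log <Rg^2> = 2*nu*log N + const over the supplied ensembles and
    returns (nu, stderr_nu).
    """
    if len(ensembles) < 2:
        raise ValueError("need ensembles at >= 2 chain lengths")
    log_n = np.log([e.n_beads for e in ensembles])
    log_rg2 = np.log([e.rg2().mean() for e in ensembles])
    if len(ensembles) > 2:
        coeffs, cov = np.polyfit(log_n, log_rg2, 1, cov=True)
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        coeffs = np.polyfit(log_n, log_rg2, 1)
        stderr = float("nan")
    return float(coeffs[0]) / 2.0, stderr / 2.0
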