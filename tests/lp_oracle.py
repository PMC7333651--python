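"""Independent LP oracle: exhaustive vertex enumeration.

Maximizes c.v over the flux polytope {v : S v = 0, lb <= v <= ub} by
enumerating candidate vertices (every choice of n - rank(S) coordinates
fixed at a bound, solving the balance equations for the rest) — no LP
solver involved, so it can cross-check one.
"""

from __future__ import annotations

import itertools

import numpy as np


def vertex_enumeration_max(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    tol: float = 1e-7,
) -> float | None:
    """Exact maximum of c.v over the bounded flux polytope.

    Returns None when no feasible vertex is found (empty polytope).
    Every vertex of the polytope has at least d = n - rank(S) active
    bound constraints whose removal leaves a uniquely solvable system;
    enumerating all (subset, bound-side) choices therefore visits every
    vertex, and a bounded feasible LP attains its optimum at one.
    """
    m, n = S.shape
    rank = int(np.linalg.matrix_rank(S)) if m else 0
    d = n - rank
    best: float | None = None
    for fixed in itertools.combinations(range(n), d):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free] if free else None
        for sides in itertools.product((0, 1), repeat=d):
            v = np.empty(n)
            v_fixed = np.array(
                [ub[j] if s else lb[j] for j, s in zip(fixed, sides)]
            )
            v[list(fixed)] = v_fixed
            if free:
                rhs = -S[:, list(fixed)] @ v_fixed if d else np.zeros(m)
                x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                v[free] = x
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def random_flux_network(rng: np.random.Generator):
    """Small random stoichiometric network with finite bounds.

    Bounds always contain zero, so the network is feasible; finite
    bounds keep the LP bounded. Columns are resampled until every
    reaction touches a metabolite.
    """
    n = int(rng.integers(4, 9))
    m = int(rng.integers(2, 6))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        if not np.any(np.all(S == 0, axis=0)):
            break
    lb = np.where(rng.random(n) < 0.5, -10.0, 0.0)
    ub = np.full(n, 10.0)
    c = np.zeros(n)
    c[int(rng.integers(n))] = 1.0
    return S, lb, ub, c


def network_to_cobra(S, lb, ub, name="random"):
    """Materialize the raw network as a cobra model (R0..Rn-1, M0..Mm-1)."""
    from cobra import Metabolite, Model, Reaction

    m, n = S.shape
    model = Model(name)
    mets = [Metabolite(f"M{i}", compartment="c") for i in range(m)]
    rxns = []
    for j in range(n):
        rxn = Reaction(f"R{j}", lower_bound=float(lb[j]), upper_bound=float(ub[j]))
        rxns.append(rxn)
    model.add_reactions(rxns)
    for j in range(n):
        rxns[j].add_metabolites(
            {mets[i]: float(S[i, j]) for i in range(m) if S[i, j] != 0}
        )
    return model
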