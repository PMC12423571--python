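"""Observed-variable path model specification.

A :class:`PathModel` describes a recursive (directed-acyclic) system of
linear structural equations among observed variables,

.. math:: y = B y + \\zeta, \\qquad \\zeta \\sim N(0, \\Psi),

where ``B`` holds the regression (path) coefficients and ``Psi`` the
residual variances and any permitted residual covariances.  Exogenous
variables have no incoming paths; their variances and mutual covariances
are free elements of ``Psi``.

Models can be written in a compact text DSL mirroring common SEM syntax::

    seed ~ footprint + mass_extant + mass_extinct + pc1 + pc2
    mass_extant ~ footprint + pc1 + pc2
    footprint ~~ mass_extinct

``a ~ b`` declares a directed path ``b -> a``; ``a ~~ b`` frees the
residual covariance between ``a`` and ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["PathModel", "parse_model", "default_downsizing_model"]


@dataclass(frozen=True)
class PathModel:
    """Recursive path model over an ordered list of observed variables.

    Parameters
    ----------
    variables:
        Ordered variable names; all matrices follow this order.
    regressions:
        Directed edges as ``(target, source)`` pairs, i.e. ``source -> target``.
    covariances:
        Unordered pairs whose residual covariance is a free parameter.
        Diagonal residual variances are always free.  The exogenous block
        (variances and covariances among exogenous variables) is free by
        construction.
    """

    variables: tuple[str, ...]
    regressions: tuple[tuple[str, str], ...]
    covariances: tuple[tuple[str, str], ...] = ()
    #: free the variances *and* covariances among exogenous variables;
    #: the independence baseline sets this False (variances only)
    free_exogenous_block: bool = True

    def __post_init__(self) -> None:
        seen = set(self.variables)
        for t, s in self.regressions:
            if t not in seen or s not in seen:
                raise ValueError(f"unknown variable in path {s} -> {t}")
        for a, b in self.covariances:
            if a not in seen or b not in seen:
                raise ValueError(f"unknown variable in covariance {a} ~~ {b}")
            if a == b:
                raise ValueError("use residual variances, not a ~~ a")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((s, t) for t, s in self.regressions)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("non-recursive model")

    # -- basic structure -------------------------------------------------
    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.variables.index(name)

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {t for t, _ in self.regressions}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {t for t, _ in self.regressions}
        return tuple(v for v in self.variables if v not in targets)

    def parents(self, name: str) -> tuple[str, ...]:
        return tuple(s for t, s in self.regressions if t == name)

    # -- free parameters -------------------------------------------------
    def free_psi_pairs(self) -> list[tuple[int, int]]:
        """Free (i, j) with i <= j of the residual covariance matrix."""
        idx = {v: k for k, v in enumerate(self.variables)}
        pairs = {(i, i) for i in range(self.n_vars)}
        if self.free_exogenous_block:
            exo = [idx[v] for v in self.exogenous]
            for a in exo:
                for b in exo:
                    if a < b:
                        pairs.add((a, b))
        for a, b in self.covariances:
            i, j = sorted((idx[a], idx[b]))
            pairs.add((i, j))
        return sorted(pairs)

    def parameter_labels(self) -> list[str]:
        labels = [f"{t}~{s}" for t, s in self.regressions]
        v = self.variables
        labels += [
            (f"{v[i]}~~{v[i]}" if i == j else f"{v[i]}~~{v[j]}")
            for i, j in self.free_psi_pairs()
        ]
        return labels

    @property
    def n_free(self) -> int:
        return len(self.regressions) + len(self.free_psi_pairs())

    def build_matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Assemble (B, Psi) from the free-parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}")
        p = self.n_vars
        idx = {v: k for k, v in enumerate(self.variables)}
        B = np.zeros((p, p))
        for k, (t, s) in enumerate(self.regressions):
            B[idx[t], idx[s]] = theta[k]
        Psi = np.zeros((p, p))
        for k, (i, j) in enumerate(self.free_psi_pairs(), start=len(self.regressions)):
            Psi[i, j] = theta[k]
            Psi[j, i] = theta[k]
        return B, Psi

    def drop_path(self, target: str, source: str) -> "PathModel":
        edge = (target, source)
        if edge not in self.regressions:
            raise ValueError(f"path {source} -> {target} not in model")
        regs = tuple(e for e in self.regressions if e != edge)
        return PathModel(self.variables, regs, self.covariances,
                         self.free_exogenous_block)

    # -- DSL -------------------------------------------------------------
    def to_dsl(self) -> str:
        lines = []
        for t in self.variables:
            ps = self.parents(t)
            if ps:
                lines.append(f"{t} ~ " + " + ".join(ps))
        for a, b in self.covariances:
            lines.append(f"{a} ~~ {b}")
        return "\n".join(lines) + "\n"


def parse_model(text: str, variables: list[str] | None = None) -> PathModel:
    """Parse the model DSL into a :class:`PathModel`.

    Variable order is first-appearance order unless ``variables`` is given.
    Lines starting with ``#`` and blank lines are ignored.
    """
    regs: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    order: list[str] = []

    def note(name: str) -> str:
        name = name.strip()
        if not name:
            raise ValueError("empty variable name in model syntax")
        if name not in order:
            order.append(name)
        return name

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~~" in line:
            left, right = line.split("~~", 1)
            a = note(left)
            for b in right.split("+"):
                covs.append((a, note(b)))
        elif "~" in line:
            left, right = line.split("~", 1)
            t = note(left)
            for s in right.split("+"):
                regs.append((t, note(s)))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    if variables is not None:
        missing = set(order) - set(variables)
        if missing:
            raise ValueError(f"model mentions unknown variables: {sorted(missing)}")
        order = list(variables)
    return PathModel(tuple(order), tuple(regs), tuple(covs))


def default_downsizing_model() -> PathModel:
    """A priori model linking human footprint, frugivore size and seed size.

    Maximum seed width responds to human footprint directly and via the
    maximum body mass of extant frugivores (downsizing cascade), and to the
    maximum body mass of extinct megafrugivores (legacy signal).  Two
    environmental principal components feed every non-exogenous variable.
    Residual covariances are allowed between footprint and extinct mass and
    between extant and extinct mass, acknowledging shared unmodelled
    drivers.
    """
    return parse_model(
        """
        seed ~ footprint + mass_extant + mass_extinct + pc1 + pc2
        mass_extant ~ footprint + pc1 + pc2
        mass_extinct ~ pc1 + pc2
        footprint ~ pc1 + pc2
        footprint ~~ mass_extinct
        mass_extant ~~ mass_extinct
        """,
        variables=["seed", "mass_extant", "mass_extinct", "footprint", "pc1", "pc2"],
    )
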