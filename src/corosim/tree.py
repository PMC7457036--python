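"""Order-structured coronary arterial trees: generation, validation, IO.

A tree is a single-rooted, acyclic network of vessels with diameter-defined
orders 0-6 (order increases with diameter; the root carries the highest
order).  Junctions are bifurcations or trifurcations, so the structural
identity n_vessels = 1 + 2·n_bif + 3·n_trif always holds.  Each vessel
carries a passive pressure-diameter law (sigmoidal in the transvascular
pressure) parameterized by the asymptotic radii Ap > Bp, the mid-range
transvascular pressure phi_p, and the bandwidth Cp.

Trees are serialized as flat tab-delimited text, one vessel per row:
``id  parent_id  order  diameter  length  Ap  Bp  phi_p  Cp``
(parent_id empty for the root; diameter/length/radii in cm, pressures mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Vessel",
    "CoronaryTree",
    "MorphometrySpec",
    "OrderStats",
    "TreeValidationError",
    "TreeParseError",
    "generate_tree",
    "assign_vessel_properties",
    "write_tree",
    "read_tree",
]

COLUMNS = ["id", "parent_id", "order", "diameter", "length", "Ap", "Bp", "phi_p", "Cp"]


class TreeValidationError(ValueError):
    """A tree (or tree spec) violates a structural invariant."""


class TreeParseError(ValueError):
    """A tree file is malformed; the message carries the line number."""


@dataclass
class Vessel:
    """One vessel segment (a row of the tree table)."""

    id: int
    parent_id: int | None
    order: int
    diameter: float  # reference diameter at transvascular pressure phi_p (cm)
    length: float  # cm
    Ap: float  # asymptotic maximal radius (cm)
    Bp: float  # asymptotic minimal radius (cm)
    phi_p: float  # transvascular pressure at the mean radius (mmHg)
    Cp: float  # passive bandwidth (mmHg)


@dataclass
class OrderStats:
    """Per-order morphometry: diameter range/mean and length range/mean (cm)."""

    d_min: float
    d_mean: float
    d_max: float
    l_min: float
    l_mean: float
    l_max: float
    phi_p: float = 65.0
    Cp: float = 25.0

    def __post_init__(self) -> None:
        if not self.d_min <= self.d_mean <= self.d_max:
            raise TreeValidationError(
                f"degenerate diameter range ({self.d_min}, {self.d_mean}, {self.d_max})"
            )
        if not 0 < self.l_min <= self.l_mean <= self.l_max:
            raise TreeValidationError(
                f"degenerate length range ({self.l_min}, {self.l_mean}, {self.l_max})"
            )
        if self.d_min <= 0:
            raise TreeValidationError("diameters must be positive")


@dataclass
class MorphometrySpec:
    """Target topology counts plus per-order morphometry tables.

    The fraction of the reference diameter assigned to the asymptotic radii
    is global: Ap = ap_frac·D, Bp = (1 − ap_frac)·D with ap_frac in (0.5, 1),
    so the reference diameter is attained at transvascular pressure phi_p.
    p_continue is the probability that one child of a junction keeps its
    parent's order instead of stepping down by one.
    """

    n_bif: int
    n_trif: int
    orders: dict[int, OrderStats]
    root_order: int = 6
    seed: int = 0
    ap_frac: float = 0.62
    p_continue: float = 0.25
    n_vessels: int | None = None

    def __post_init__(self) -> None:
        if self.n_bif < 0 or self.n_trif < 0:
            raise TreeValidationError("junction counts must be non-negative")
        implied = 1 + 2 * self.n_bif + 3 * self.n_trif
        if self.n_vessels is None:
            self.n_vessels = implied
        elif self.n_vessels != implied:
            raise TreeValidationError(
                "inconsistent counts: n_vessels must equal 1 + 2*n_bif + 3*n_trif "
                f"= {implied}, got {self.n_vessels}"
            )
        if not 0.5 < self.ap_frac < 1.0:
            raise TreeValidationError(f"ap_frac must be in (0.5, 1), got {self.ap_frac}")
        if self.root_order not in self.orders:
            raise TreeValidationError(f"no morphometry for root order {self.root_order}")
        for o in self.orders:
            if not 0 <= o <= 6:
                raise TreeValidationError(f"order {o} outside [0, 6]")


class CoronaryTree:
    """Vector storage of a validated coronary tree.

    Attributes are parallel arrays indexed by vessel position; ``parent`` is
    −1 for the root.  ``ids`` are arbitrary unique integers (generated trees
    use 0..n−1).
    """

    def __init__(self, ids, parent, order, diameter, length, Ap, Bp, phi_p, Cp):
        self.ids = np.asarray(ids, dtype=int)
        self.parent = np.asarray(parent, dtype=int)
        self.order = np.asarray(order, dtype=int)
        self.diameter = np.asarray(diameter, dtype=float)
        self.length = np.asarray(length, dtype=float)
        self.Ap = np.asarray(Ap, dtype=float)
        self.Bp = np.asarray(Bp, dtype=float)
        self.phi_p = np.asarray(phi_p, dtype=float)
        self.Cp = np.asarray(Cp, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_vessels(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def child_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_vessels, dtype=int)
        np.add.at(counts, self.parent[self.parent >= 0], 1)
        return counts

    @property
    def is_leaf(self) -> np.ndarray:
        return self.child_counts == 0

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def n_bifurcations(self) -> int:
        return int((self.child_counts == 2).sum())

    @property
    def n_trifurcations(self) -> int:
        return int((self.child_counts == 3).sum())

    def vessels(self):
        """Iterate over Vessel records (file order)."""
        for i in range(self.n_vessels):
            pid = None if self.parent[i] < 0 else int(self.ids[self.parent[i]])
            yield Vessel(
                int(self.ids[i]), pid, int(self.order[i]), float(self.diameter[i]),
                float(self.length[i]), float(self.Ap[i]), float(self.Bp[i]),
                float(self.phi_p[i]), float(self.Cp[i]),
            )

    def validate(self) -> None:
        n = self.n_vessels
        if n == 0:
            raise TreeValidationError("empty tree")
        if len(np.unique(self.ids)) != n:
            raise TreeValidationError("duplicate vessel ids")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeValidationError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.parent >= n):
            raise TreeValidationError("parent index out of range")
        # connectivity/acyclicity: every vessel must reach the root
        depth = np.full(n, -1, dtype=int)
        for i in range(n):
            j, hops = i, 0
            while depth[j] < 0 and self.parent[j] >= 0 and hops <= n:
                j = self.parent[j]
                hops += 1
            if hops > n:
                raise TreeValidationError("cycle detected")
            if self.parent[j] < 0 or depth[j] >= 0:
                depth[i] = 0  # reachable
            else:  # pragma: no cover - unreachable by construction
                raise TreeValidationError("disconnected vessel")
        nonroot = self.parent >= 0
        if np.any(self.order[nonroot] > self.order[self.parent[nonroot]]):
            raise TreeValidationError("child order exceeds parent order")
        arity = self.child_counts
        bad = ~np.isin(arity, (0, 2, 3))
        if np.any(bad):
            raise TreeValidationError(
                f"junction arity must be 2 or 3, found arity {arity[bad][0]}"
            )
        if np.any(self.Ap <= self.Bp) or np.any(self.Bp <= 0):
            raise TreeValidationError("require Ap > Bp > 0 for every vessel")
        if np.any(self.length <= 0):
            raise TreeValidationError("vessel lengths must be positive")
        if np.any((self.order < 0) | (self.order > 6)):
            raise TreeValidationError("orders must lie in [0, 6]")

    # -- convenience -------------------------------------------------------
    def poiseuille_resistance(self, mu: float) -> float:
        """Total tree resistance (mmHg·s/ml) at reference diameters.

        Series/parallel reduction of full-vessel Poiseuille resistances
        128·mu·L/(pi·D^4); a design/diagnostic aid, not the flow solver.
        """
        R = 128.0 * mu * self.length / (np.pi * self.diameter**4)
        order_idx = np.argsort(-self._depths())  # leaves first
        g_sub = np.zeros(self.n_vessels)  # conductance of subtree below vessel
        for i in order_idx:
            p = self.parent[i]
            r_tot = R[i] + (1.0 / g_sub[i] if g_sub[i] > 0 else 0.0)
            if p >= 0:
                g_sub[p] += 1.0 / r_tot
        r = self.root
        return R[r] + (1.0 / g_sub[r] if g_sub[r] > 0 else 0.0)

    def _depths(self) -> np.ndarray:
        d = np.zeros(self.n_vessels, dtype=int)
        for i in range(self.n_vessels):
            j = i
            while self.parent[j] >= 0:
                d[i] += 1
                j = self.parent[j]
        return d


def generate_tree(spec: MorphometrySpec) -> CoronaryTree:
    """Grow a tree with exactly the requested junction counts.

    Junction arities are shuffled and applied to the highest-order open leaf
    (ties broken randomly), producing an order cascade from the root down;
    children step down one order with one child optionally continuing the
    parent's order.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    arities = np.array([2] * spec.n_bif + [3] * spec.n_trif)
    rng.shuffle(arities)

    parent = [-1]
    order = [spec.root_order]
    open_leaves = [0]
    for a in arities:
        omax = max(order[i] for i in open_leaves)
        top = [i for i in open_leaves if order[i] == omax]
        v = top[int(rng.integers(len(top)))]
        open_leaves.remove(v)
        child_orders = np.full(a, max(order[v] - 1, 0))
        if order[v] > 0 and rng.random() < spec.p_continue:
            child_orders[int(rng.integers(a))] = order[v]
        for co in child_orders:
            parent.append(v)
            order.append(int(co))
            open_leaves.append(len(parent) - 1)

    n = len(parent)
    ids = np.arange(n)
    tree = CoronaryTree(
        ids, parent, order,
        diameter=np.ones(n), length=np.ones(n),
        Ap=np.full(n, 0.62), Bp=np.full(n, 0.38),
        phi_p=np.full(n, 65.0), Cp=np.full(n, 25.0),
    )
    return assign_vessel_properties(tree, spec, rng=rng)


def assign_vessel_properties(
    tree: CoronaryTree, spec: MorphometrySpec, rng: np.random.Generator | None = None
) -> CoronaryTree:
    """Sample per-vessel diameters/lengths from the per-order tables.

    Uniform samples within each order's range are recentered so the sample
    mean matches the configured mean exactly (then clipped to the range);
    the pressure-diameter constants follow from the sampled diameter via
    Ap = ap_frac·D, Bp = (1 − ap_frac)·D and the order's phi_p, Cp.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = tree.n_vessels
    D = np.empty(n)
    L = np.empty(n)
    phi = np.empty(n)
    Cp = np.empty(n)
    for o in np.unique(tree.order):
        if int(o) not in spec.orders:
            raise TreeValidationError(f"no morphometry configured for order {o}")
        st = spec.orders[int(o)]
        m = tree.order == o
        k = int(m.sum())
        d = rng.uniform(st.d_min, st.d_max, size=k)
        d = np.clip(d + (st.d_mean - d.mean()), st.d_min, st.d_max)
        ln = rng.uniform(st.l_min, st.l_max, size=k)
        ln = np.clip(ln + (st.l_mean - ln.mean()), st.l_min, st.l_max)
        D[m], L[m] = d, ln
        phi[m], Cp[m] = st.phi_p, st.Cp
    return CoronaryTree(
        tree.ids, tree.parent, tree.order, D, L,
        Ap=spec.ap_frac * D, Bp=(1.0 - spec.ap_frac) * D, phi_p=phi, Cp=Cp,
    )


def write_tree(tree: CoronaryTree, path) -> None:
    """Serialize a tree to the flat tab-delimited format."""
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for v in tree.vessels():
            pid = "" if v.parent_id is None else str(v.parent_id)
            fh.write(
                f"{v.id}\t{pid}\t{v.order}\t{v.diameter!r}\t{v.length!r}\t"
                f"{v.Ap!r}\t{v.Bp!r}\t{v.phi_p!r}\t{v.Cp!r}\n"
            )


def read_tree(path) -> CoronaryTree:
    """Parse and validate a tree file; round-trips :func:`write_tree` exactly."""
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != COLUMNS:
            raise TreeParseError(f"line 1: expected header {COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(COLUMNS):
                raise TreeParseError(
                    f"line {lineno}: expected {len(COLUMNS)} fields, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        int(parts[0]),
                        None if parts[1] == "" else int(parts[1]),
                        int(parts[2]),
                        *(float(p) for p in parts[3:]),
                    )
                )
            except ValueError as exc:
                raise TreeParseError(f"line {lineno}: {exc}") from exc
    if not rows:
        raise TreeParseError("line 2: file contains no vessels")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise TreeParseError("duplicate vessel ids in file")
    pos = {vid: i for i, vid in enumerate(ids)}
    parent = []
    for r in rows:
        if r[1] is None:
            parent.append(-1)
        elif r[1] not in pos:
            raise TreeParseError(f"vessel {r[0]} references unknown parent {r[1]} (orphan)")
        else:
            parent.append(pos[r[1]])
    cols = list(zip(*rows))
    return CoronaryTree(
        ids, parent, cols[2], cols[3], cols[4], cols[5], cols[6], cols[7], cols[8]
    )
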