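"""Bond-fluctuation-method (BFM) lattice core: two self-avoiding ring polymers
in a rod-shaped box.

The model represents each sister chromosome as a closed ring of ``N`` coarse
monomers on a cubic lattice.  A monomer at integer position ``p`` occupies the
8 lattice sites of the unit cube ``p + {0,1}^3`` (cube center ``p + 0.5``);
bonds between consecutive ring monomers are restricted to the standard 3D BFM
vector set (squared lengths {4, 5, 6, 9, 10}), which together with single-site
excluded volume guarantees that chains can never cross.  The confining box has
hard walls: no cube may extend outside ``[0, Lx] x [0, Ly] x [0, Lz]``, so
positions run ``0 .. L-1`` per axis.

Dynamics are single-monomer displacements by one lattice unit along one of the
6 axial directions, accepted only if excluded volume, wall, bond and tether
constraints all hold.  One Monte-Carlo step (MCS) is ``M`` attempted moves
(``M`` = total monomers), after which the membrane-tether field is updated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._kernel import run_kernel

__all__ = [
    "ALLOWED_BOND_SQUARED_LENGTHS",
    "ConfinementBox",
    "RingPolymer",
    "MoveProposal",
    "SystemState",
    "allowed_bond_set",
    "is_allowed_bond",
    "attempt_move",
    "run_mcs",
    "init_overlapping_rings",
    "axial_cm",
    "RunRecord",
]

ALLOWED_BOND_SQUARED_LENGTHS = frozenset({4, 5, 6, 9, 10})

_BASE_BOND_VECTORS = [(2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0), (3, 1, 0)]

#: unit lattice directions for MoveProposal
DIRECTIONS = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]], dtype=np.int64
)


def allowed_bond_set() -> frozenset:
    """All permutations and sign combinations of the 6 BFM base bond vectors.

    Returns the classic 108-vector set; membership is equivalent to the bond's
    squared length lying in {4, 5, 6, 9, 10}.
    """
    out = set()
    for base in _BASE_BOND_VECTORS:
        for perm in itertools.permutations(base):
            for signs in itertools.product((1, -1), repeat=3):
                out.add(tuple(c * s for c, s in zip(perm, signs)))
    return frozenset(out)


def is_allowed_bond(vec) -> bool:
    """True iff ``vec`` is in the allowed BFM bond set."""
    s = int(vec[0]) ** 2 + int(vec[1]) ** 2 + int(vec[2]) ** 2
    return s in ALLOWED_BOND_SQUARED_LENGTHS


@dataclass(frozen=True)
class ConfinementBox:
    """Hard-walled rectangular box; defaults give the 1:8 rod (80 x 10 x 10)."""

    Lx: int = 80
    Ly: int = 10
    Lz: int = 10

    def __post_init__(self):
        for name in ("Lx", "Ly", "Lz"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 2):
                raise ValueError(f"{name} must be an integer >= 2, got {v!r}")

    @property
    def dims(self):
        return (self.Lx, self.Ly, self.Lz)


@dataclass
class RingPolymer:
    """One chromosome: an ordered closed ring of monomer positions.

    ``positions`` holds the lower-corner lattice coordinates, shape (N, 3).
    """

    positions: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3 or len(self.positions) < 3:
            raise ValueError("positions must be an (N>=3, 3) integer array")

    @property
    def N(self) -> int:
        return len(self.positions)

    def bonds(self) -> np.ndarray:
        """Cyclic bond vectors, bond i = positions[i+1] - positions[i]."""
        return np.roll(self.positions, -1, axis=0) - self.positions


@dataclass(frozen=True)
class MoveProposal:
    polymer_id: int
    monomer_index: int
    direction: tuple  # one of the 6 axial unit vectors

    def __post_init__(self):
        d = tuple(int(c) for c in self.direction)
        if sorted(abs(c) for c in d) != [0, 0, 1]:
            raise ValueError(f"direction must be an axial unit vector, got {d}")
        object.__setattr__(self, "direction", d)


@dataclass
class RunRecord:
    """What came back from a :func:`run_mcs` call."""

    mcs_points: np.ndarray          # (T,) MCS clock values of the recorded rows
    cm_rel: np.ndarray              # (T, n_polymers) relative axial CM
    bind_counts_x: np.ndarray       # (Lx,) binding events per axial position
    n_bind_events: int
    mean_drawn_dwell: float         # mean of the drawn dwell durations (MCS)
    events: np.ndarray | None = None  # optional (k, 4) log: mcs, polymer, monomer, x


class SystemState:
    """Full mutable simulation state: rings, occupancy, tethers, clock, RNG.

    Parameters
    ----------
    box : ConfinementBox
    polymers : list of (N, 3) arrays or RingPolymer (1 or 2 rings, equal N)
    rng : numpy Generator or int seed
    interchain_exclusion : bool
        When False, excluded volume between the two rings is switched off
        (each ring remains self-avoiding); models the entropy-off control.
    """

    def __init__(self, box, polymers, rng, interchain_exclusion=True, labels=None, mcs_clock=0):
        self.box = box
        arrays = []
        for p in polymers:
            arrays.append(p.positions if isinstance(p, RingPolymer) else np.asarray(p))
        if len(arrays) not in (1, 2):
            raise ValueError("SystemState holds 1 or 2 rings")
        if len({len(a) for a in arrays}) != 1:
            raise ValueError("all rings must have the same length")
        self.N = len(arrays[0])
        self.n_polymers = len(arrays)
        self.pos = np.ascontiguousarray(np.concatenate(arrays), dtype=np.int64)
        self.rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.interchain_exclusion = bool(interchain_exclusion)
        if labels is None:
            labels = ["left", "right"][: self.n_polymers]
        self.labels = list(labels)
        self.mcs_clock = int(mcs_clock)
        self.tethered = np.zeros(self.M, dtype=bool)
        self.release_mcs = np.zeros(self.M, dtype=np.int64)
        self.occupancy = self._build_occupancy()

    # -- basic structure ---------------------------------------------------

    @property
    def M(self) -> int:
        return self.N * self.n_polymers

    @property
    def polymers(self):
        return [
            RingPolymer(self.pos[p * self.N : (p + 1) * self.N].copy(), self.labels[p])
            for p in range(self.n_polymers)
        ]

    def polymer_positions(self, p: int) -> np.ndarray:
        return self.pos[p * self.N : (p + 1) * self.N]

    def _build_occupancy(self) -> np.ndarray:
        Lx, Ly, Lz = self.box.dims
        occ = np.zeros((2, Lx + 1, Ly + 1, Lz + 1), dtype=np.uint8)
        for i in range(self.M):
            p = i // self.N
            x, y, z = self.pos[i]
            occ[p, x : x + 2, y : y + 2, z : z + 2] += 1
        return occ

    def copy(self) -> "SystemState":
        new = SystemState.__new__(SystemState)
        new.box = self.box
        new.N = self.N
        new.n_polymers = self.n_polymers
        new.pos = self.pos.copy()
        new.rng = np.random.default_rng()
        new.rng.bit_generator.state = self.rng.bit_generator.state
        new.interchain_exclusion = self.interchain_exclusion
        new.labels = list(self.labels)
        new.mcs_clock = self.mcs_clock
        new.tethered = self.tethered.copy()
        new.release_mcs = self.release_mcs.copy()
        new.occupancy = self.occupancy.copy()
        return new

    # -- validation --------------------------------------------------------

    def validate(self):
        """Full revalidation of every structural invariant; raises on violation."""
        Lx, Ly, Lz = self.box.dims
        lims = np.array([Lx - 1, Ly - 1, Lz - 1])
        if (self.pos < 0).any() or (self.pos > lims).any():
            raise AssertionError("monomer cube extends outside the box")
        for p in range(self.n_polymers):
            ring = RingPolymer(self.polymer_positions(p))
            sq = (ring.bonds() ** 2).sum(axis=1)
            if not all(int(s) in ALLOWED_BOND_SQUARED_LENGTHS for s in sq):
                raise AssertionError(f"ring {p} has a bond outside the BFM set")
            # intra-chain excluded volume: cube overlap iff all |delta| <= 1
            pp = self.polymer_positions(p)
            d = np.abs(pp[:, None, :] - pp[None, :, :]).max(axis=2)
            np.fill_diagonal(d, 99)
            if (d <= 1).any():
                raise AssertionError(f"ring {p} violates self-avoidance")
        if self.n_polymers == 2 and self.interchain_exclusion:
            a = self.polymer_positions(0)
            b = self.polymer_positions(1)
            d = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)
            if (d <= 1).any():
                raise AssertionError("rings violate mutual excluded volume")
        if not np.array_equal(self.occupancy, self._build_occupancy()):
            raise AssertionError("occupancy map inconsistent with positions")
        if (self.occupancy > 1).any():
            raise AssertionError("a lattice site is claimed twice within one ring")
        bound = self.tethered
        if bound.any() and (self.release_mcs[bound] <= 0).any():
            raise AssertionError("bound monomer without a release time")
        return True

    # -- plain-text snapshots ---------------------------------------------

    def to_table(self, path):
        """Write the configuration as tabular text for restart/fixtures."""
        import pandas as pd

        rows = []
        for i in range(self.M):
            p = i // self.N
            rows.append((p, i - p * self.N, *self.pos[i]))
        df = pd.DataFrame(rows, columns=["polymer_id", "monomer_index", "x", "y", "z"])
        with open(path, "w") as fh:
            fh.write(
                f"# box: {self.box.Lx} {self.box.Ly} {self.box.Lz}"
                f" interchain_exclusion: {int(self.interchain_exclusion)}"
                f" labels: {','.join(self.labels)}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_table(cls, path, rng=0):
        import pandas as pd

        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# box:"):
                raise ValueError(f"{path}: missing '# box:' header line")
            toks = header.split()
            box = ConfinementBox(int(toks[2]), int(toks[3]), int(toks[4]))
            inter = bool(int(toks[6]))
            labels = toks[8].split(",")
            df = pd.read_csv(fh)
        df = df.sort_values(["polymer_id", "monomer_index"])
        arrays = [
            g[["x", "y", "z"]].to_numpy(dtype=np.int64)
            for _, g in df.groupby("polymer_id", sort=True)
        ]
        return cls(box, arrays, rng, interchain_exclusion=inter, labels=labels)


# -- the elementary move (pure-Python reference) ---------------------------


def attempt_move(state: SystemState, proposal: MoveProposal) -> bool:
    """Try one single-monomer displacement; mutate ``state`` iff accepted.

    Acceptance requires all of: the monomer is not tethered, the displaced
    cube stays inside the box, the four target sites are free (cross-ring
    occupancy ignored when ``interchain_exclusion`` is off), and both ring
    bonds stay in the allowed BFM set.
    """
    p, m = proposal.polymer_id, proposal.monomer_index
    if not (0 <= p < state.n_polymers and 0 <= m < state.N):
        raise IndexError("polymer or monomer index out of range")
    i = p * state.N + m
    if state.tethered[i]:
        return False
    d = np.array(proposal.direction, dtype=np.int64)
    new = state.pos[i] + d
    lims = np.array([state.box.Lx - 1, state.box.Ly - 1, state.box.Lz - 1])
    if (new < 0).any() or (new > lims).any():
        return False
    axis = int(np.nonzero(d)[0][0])
    sgn = int(d[axis])
    # leading plane of 4 sites in the direction of motion
    lead = state.pos[i, axis] + (2 if sgn > 0 else -1)
    idx = [slice(c, c + 2) for c in state.pos[i]]
    idx[axis] = slice(lead, lead + 1)
    if state.occupancy[(p, *idx)].any():
        return False
    if state.interchain_exclusion and state.n_polymers == 2 and state.occupancy[(1 - p, *idx)].any():
        return False
    prev = p * state.N + (m - 1) % state.N
    nxt = p * state.N + (m + 1) % state.N
    if not is_allowed_bond(state.pos[prev] - new) or not is_allowed_bond(state.pos[nxt] - new):
        return False
    # accept
    old = state.pos[i].copy()
    clear = [slice(c, c + 2) for c in old]
    clear[axis] = slice(old[axis] if sgn > 0 else old[axis] + 1, (old[axis] if sgn > 0 else old[axis] + 1) + 1)
    state.occupancy[(p, *clear)] = 0
    set_ = [slice(c, c + 2) for c in new]
    set_[axis] = slice(new[axis] + 1 if sgn > 0 else new[axis], (new[axis] + 1 if sgn > 0 else new[axis]) + 1)
    state.occupancy[(p, *set_)] = 1
    state.pos[i] = new
    return True


# -- the MCS loop (numba path) ---------------------------------------------


def run_mcs(
    state: SystemState,
    field_spec=None,
    n_mcs: int = 0,
    record_every: int = 0,
    force: float = 0.0,
    cm_limit: float = 0.0,
    log_events: int = 0,
) -> RunRecord:
    """Advance ``state`` by ``n_mcs`` Monte-Carlo steps.

    ``field_spec`` is a :class:`minratchet.tethering.TetherFieldSpec` (or None
    for no tethering).  ``force`` adds the attractive inter-ring potential
    ``U = f * d`` (d = axial CM separation, energies in kT) accepted through a
    Metropolis layer on top of the hard constraints.  ``cm_limit`` constrains
    each ring's axial CM to within that many lattice units of mid-cell
    (used by the mixing initializer).  ``log_events`` > 0 records up to that
    many individual binding events.
    """
    from .tethering import TetherFieldSpec, build_field_table

    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    spec = field_spec if field_spec is not None else TetherFieldSpec(mode="none")
    table, slot_of_mcs = build_field_table(spec, state.box)
    Lx, Ly, Lz = state.box.dims
    n_rec = n_mcs // record_every if record_every else 0
    cm_out = np.zeros((n_rec, state.n_polymers), dtype=np.float64)
    bind_x = np.zeros(Lx, dtype=np.int64)
    events = np.zeros((int(log_events), 4), dtype=np.int64)
    clock, n_ev, dwell_sum, got, n_logged = run_kernel(
        state.pos,
        state.occupancy,
        state.tethered,
        state.release_mcs,
        np.int64(state.mcs_clock),
        np.int64(n_mcs),
        np.int64(Lx),
        np.int64(Ly),
        np.int64(Lz),
        np.int64(state.n_polymers),
        np.int64(state.N),
        bool(state.interchain_exclusion),
        table,
        slot_of_mcs,
        float(spec.dwell_mean),
        np.int64(spec.border_distance),
        float(force),
        float(cm_limit),
        np.int64(record_every),
        cm_out,
        bind_x,
        events,
        state.rng,
    )
    start = state.mcs_clock
    state.mcs_clock = int(clock)
    if record_every:
        pts = start + record_every * np.arange(1, got + 1)
    else:
        pts = np.array([], dtype=np.int64)
    return RunRecord(
        mcs_points=pts,
        cm_rel=cm_out[: int(got)],
        bind_counts_x=bind_x,
        n_bind_events=int(n_ev),
        mean_drawn_dwell=(dwell_sum / n_ev) if n_ev else float("nan"),
        events=events[: int(n_logged)] if log_events else None,
    )


# -- initialization --------------------------------------------------------


def _grid_cycle(a: int, b: int, c: int) -> np.ndarray:
    """Hamiltonian cycle through the a x b x c grid (a even, c in {1, 2}).

    Construction: a 'rail' runs along x at (y=0, z=0); at each x the
    remaining cells of the y-z plane are traversed by a fixed serpentine
    path, reversed on odd x so that consecutive planes join.
    """
    if a % 2 != 0 or a < 2 or b < 2 or c not in (1, 2):
        raise ValueError(f"unsupported grid {a}x{b}x{c}")
    if c == 1:
        plane = [(y, 0) for y in range(1, b)]
    else:
        plane = [(y, 0) for y in range(1, b)] + [(y, 1) for y in range(b - 1, 0, -1)] + [(0, 1)]
    nodes = []
    for x in range(a):
        seq = plane if x % 2 == 0 else plane[::-1]
        nodes.extend((x, y, z) for (y, z) in seq)
    nodes.extend((x, 0, 0) for x in range(a - 1, -1, -1))
    assert len(nodes) == a * b * c
    return np.array(nodes, dtype=np.int64)


def _template_rings(box: ConfinementBox, N: int):
    """Two stacked ring templates, axially centered and fully overlapping.

    Rings are laid on a spacing-2 grid (all bonds of type (2,0,0)), side by
    side along z.  Raises with a diagnostic if no grid factorization of N
    fits the box.
    """
    Lx, Ly, Lz = box.dims
    best = None
    for c in (2, 1):
        for b in range(2, N + 1):
            if N % (b * c):
                continue
            a = N // (b * c)
            if a < 2 or a % 2:
                continue
            if 2 * (a - 1) + 1 > Lx:
                continue
            if 2 * (b - 1) + 1 > Ly:
                continue
            # two rings stacked in z, ring 1 offset by 2*c: top cube reaches 4c-1
            if 4 * c - 1 > Lz:
                continue
            # prefer the most compact axial extent with the fewest z layers needed
            key = (2 * (a - 1), -b)
            if best is None or key < best[0]:
                best = (key, (a, b, c))
    if best is None:
        raise ValueError(
            f"no valid double-ring template for N={N} in box {Lx}x{Ly}x{Lz}: box too small"
        )
    a, b, c = best[1]
    cyc = _grid_cycle(a, b, c)
    x0 = (Lx - (2 * (a - 1) + 1)) // 2
    y0 = (Ly - (2 * (b - 1) + 1)) // 2
    z0 = max(0, (Lz - (4 * c - 1)) // 2)
    ring0 = cyc * 2 + np.array([x0, y0, z0])
    ring1 = ring0 + np.array([0, 0, 2 * c])
    return ring0, ring1


def axial_cm(positions: np.ndarray) -> float:
    """Mean monomer-center x coordinate."""
    return float(positions[:, 0].mean() + 0.5)


def init_overlapping_rings(
    box: ConfinementBox,
    N: int,
    seed,
    interchain_exclusion: bool = True,
    n_mix: int = 1000,
    eps_cm: float = 1.0,
) -> SystemState:
    """Build the t=0 state: two intermixed rings centered at mid-cell.

    A deterministic template (two stacked rings, axial centers at mid-cell,
    axial extents fully overlapping) is randomized by ``n_mix`` tether-free
    mixing sweeps during which any x-move that would take either ring's
    axial CM farther than ``eps_cm`` from mid-cell is rejected.  Deterministic
    given ``seed``; left/right labels are assigned from the sign of
    (CM_x - Lx/2) after mixing, ties broken by the RNG.
    """
    ring0, ring1 = _template_rings(box, N)
    rng = np.random.default_rng(seed)
    state = SystemState(box, [ring0, ring1], rng, interchain_exclusion=interchain_exclusion)
    if n_mix:
        run_mcs(state, None, n_mcs=n_mix, cm_limit=eps_cm)
        state.mcs_clock = 0
    half = box.Lx / 2
    cms = [axial_cm(state.polymer_positions(p)) for p in range(2)]
    for p, cm in enumerate(cms):
        if abs(cm - half) > eps_cm:
            raise RuntimeError(f"initialization failed: ring {p} CM {cm} beyond {eps_cm} of {half}")
    ext = [
        (state.polymer_positions(p)[:, 0].min(), state.polymer_positions(p)[:, 0].max() + 1)
        for p in range(2)
    ]
    lo = max(e[0] for e in ext)
    hi = min(e[1] for e in ext)
    smaller = min(e[1] - e[0] for e in ext)
    if hi - lo < 0.5 * smaller:
        raise RuntimeError("initialization failed: axial extents do not overlap enough")
    if cms[0] < cms[1] or (cms[0] == cms[1] and rng.random() < 0.5):
        state.labels = ["left", "right"]
    else:
        state.labels = ["right", "left"]
    state.validate()
    return state
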