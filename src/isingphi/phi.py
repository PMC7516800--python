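"""Integrated information (IIT 3.0) of a synchronous Markov kernel.

Given the state-by-node TPM of the synchronous Ising dynamics and the current
spin configuration, this module computes the integrated conceptual
information Phi of the whole system, following the IIT 3.0 algorithm of the
published reference toolbox:

1. For every nonempty *mechanism* (subset of nodes in its current state),
   find the maximally irreducible cause and effect: over every candidate
   *purview*, compare the cause/effect repertoire against the closest
   factorized repertoire over all mechanism/purview bipartitions (the
   mechanism-level minimum-information partition, MIP), using the earth-mover
   distance with Hamming ground metric; small phi is the best purview's MIP
   distance, and the concept's phi is the minimum of the cause and effect
   values.
2. The cause-effect structure (CES) is the set of concepts with phi > 0.
3. Big Phi is the distance between the CES of the intact system and the CES
   under the *minimum unidirectional system cut* -- the bipartition
   (A -> B) severing connections from A to B that changes the structure
   least.  CES distance is a generalized EMD in concept space whose ground
   metric is the sum of cause- and effect-repertoire EMDs, with destroyed
   concepts transported to the "null concept" (the unconstrained
   repertoires).

Distances are rounded to 1e-6 (the reference toolbox's precision), which
makes minimum/maximum selections reproducible across implementations.

Exact cut-sharing
-----------------
Severing a connection k -> m replaces node m's dependence on k by
maximum-entropy noise -- exactly the marginalization already applied to every
input outside the purview (cause side) or outside the mechanism (effect
side).  A repertoire over (mechanism M, purview Z) therefore depends on a cut
only through the severed pairs *inside* Z x M (cause) or M x Z (effect).
Mechanism-level MIPs are cached under that signature and shared across all
system cuts (and across system states, through the mechanism's own state),
which is what makes temperature sweeps with per-state caching feasible.
Node subsets and cut sides are carried as little-endian bitmasks internally,
so signatures are plain integer intersections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np

from .emd import hamming_emd, hamming_emd_diff, transport_cost
from .simulation import SimulationTrace
from .states import code_to_spins, spins_to_code
from .tpm import StateByNodeTPM, expand_to_state_by_state, stationary_distribution

__all__ = [
    "Mechanism",
    "Repertoire",
    "Concept",
    "CauseEffectStructure",
    "PhiResult",
    "PhiTraceResult",
    "cause_repertoire",
    "effect_repertoire",
    "repertoire_emd",
    "small_phi",
    "compute_ces",
    "big_phi",
    "phi_over_trace",
    "clear_caches",
]

#: Matching the reference toolbox: distances are rounded to this many
#: decimals and phi values below 10**-PRECISION are zero.
PRECISION = 6

#: The MIP search is super-exponential; five nodes is the practical limit
#: (and the study's system size).
MAX_PHI_NODES = 5

CAUSE = "cause"
EFFECT = "effect"

#: Cuts are (from_mask, to_mask) bitmask pairs; (0, 0) is the intact system.
_NULL_CUT = (0, 0)


# ---------------------------------------------------------------------------
# public result containers


@dataclass(frozen=True)
class Mechanism:
    """A subset of nodes in its current state."""

    nodes: tuple[int, ...]
    state: tuple[int, ...]  # spins (+1/-1) of those nodes

    def __post_init__(self):
        if not self.nodes:
            raise ValueError("mechanism must be nonempty")
        if len(self.nodes) != len(self.state) or any(
            s not in (-1, 1) for s in self.state
        ):
            raise ValueError("mechanism state must be +-1 per node")


@dataclass(frozen=True)
class Repertoire:
    """A probability distribution over the states of a purview.

    ``distribution[k]`` is the probability of the purview state whose
    little-endian code over the ordered purview nodes is ``k``.
    """

    purview: tuple[int, ...]
    distribution: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distribution, dtype=float)
        if d.size != 2 ** len(self.purview):
            raise ValueError("distribution size must be 2**len(purview)")
        if np.any(d < -1e-12):
            raise ValueError("repertoire must be nonnegative")
        object.__setattr__(self, "distribution", d)


@dataclass(frozen=True)
class MaximallyIrreducible:
    """One side (cause or effect) of a concept."""

    direction: str
    phi: float
    purview: tuple[int, ...]
    repertoire: Repertoire | None


@dataclass(frozen=True)
class Concept:
    mechanism: tuple[int, ...]
    mechanism_state: tuple[int, ...]
    cause: MaximallyIrreducible
    effect: MaximallyIrreducible

    @property
    def phi(self) -> float:
        return min(self.cause.phi, self.effect.phi)


@dataclass(frozen=True)
class CauseEffectStructure:
    state_code: int
    concepts: tuple[Concept, ...]

    def __len__(self):
        return len(self.concepts)


@dataclass(frozen=True)
class PhiResult:
    phi: float
    system_mip: tuple[tuple[int, ...], tuple[int, ...]] | None
    state_code: int
    temperature: float
    n_concepts: int
    from_cache: bool = False


@dataclass(frozen=True)
class PhiTraceResult:
    """Phi summarized over a simulation trace."""

    phi_mean: float
    chi_phi: float
    phi_by_state: dict[int, float]
    weighting: str
    n_evaluations: int  # distinct states actually computed
    n_cache_hits: int


# ---------------------------------------------------------------------------
# small combinatorial helpers (orderings matter for tie-breaking and are kept
# identical to the reference toolbox)


def _powerset(nodes, nonempty=False):
    rng = range(0 if not nonempty else 1, len(nodes) + 1)
    return list(chain.from_iterable(combinations(nodes, r) for r in rng))


def _bipartition_indices(n):
    result = []
    for i in range(2 ** (n - 1) if n > 0 else 0):
        part = ([], [])
        for k in range(n):
            part[(i >> k) & 1].append(k)
        result.append((tuple(part[1]), tuple(part[0])))
    return result


def _bipartitions(seq):
    seq = tuple(seq)
    return [
        (tuple(seq[i] for i in a), tuple(seq[j] for j in b))
        for a, b in _bipartition_indices(len(seq))
    ]


def _directed_bipartitions(seq, nontrivial=False):
    idx = _bipartition_indices(len(seq))
    idx = idx + [p[::-1] for p in idx[::-1]]
    seq = tuple(seq)
    parts = [
        (tuple(seq[i] for i in a), tuple(seq[j] for j in b)) for a, b in idx
    ]
    return parts[1:-1] if nontrivial else parts


def _mip_bipartitions(mechanism, purview):
    """All mechanism/purview bipartitions evaluated in the MIP search."""
    out = []
    for n0, n1 in _bipartitions(mechanism):
        for d0, d1 in _directed_bipartitions(purview):
            if (n0 or d0) and (n1 or d1):
                out.append(((n0, d0), (n1, d1)))
    return out


def _block_cm(cm):
    """Whether a binary blockwise connectivity pattern is separable."""
    if np.any(cm.sum(1) == 0):
        return True
    if np.all(cm.sum(1) == 1):
        return True
    outputs = np.arange(cm.shape[1])

    def outputs_of(nodes):
        return np.where(cm[nodes, :].sum(0))[0]

    def inputs_to(nodes):
        return np.where(cm[:, nodes].sum(1))[0]

    sources = np.array([np.argmax(cm.sum(1))])
    sinks = outputs_of(sources)
    sink_inputs = inputs_to(sinks)
    while True:
        if np.array_equal(sink_inputs, sources):
            return True
        sources = sink_inputs
        sinks = outputs_of(sources)
        sink_inputs = inputs_to(sinks)
        if np.array_equal(sinks, outputs):
            return False


def _block_reducible(cm, rows, cols):
    """Whether connections from ``rows`` to ``cols`` factorize trivially."""
    if not rows or not cols:
        return True
    sub = cm[np.ix_(rows, cols)]
    if not sub.sum(0).all() or not sub.sum(1).all():
        return True
    if len(rows) > 1 and len(cols) > 1:
        return _block_cm(sub)
    return False


def _round(x: float) -> float:
    return round(x, PRECISION)


# ---------------------------------------------------------------------------
# the engine


class PhiEngine:
    """All Phi-related computation and caching for one state-by-node TPM.

    Caches are keyed by the mechanism's own state bits and by integer cut
    *signatures* (the severed connections that actually intersect a
    mechanism/purview pair), so work is shared across system states, across
    system cuts, and across a temperature sweep's repeated queries.
    Mechanism states are carried as absolute bitmasks (``mbits = state_code &
    mechanism_mask``), which makes sub-mechanism states free to derive.
    """

    def __init__(self, tpm: StateByNodeTPM):
        self.tpm = tpm
        self.n = tpm.n_nodes
        if self.n > MAX_PHI_NODES:
            raise ValueError(
                f"Phi computation is limited to {MAX_PHI_NODES} nodes "
                f"(cost grows super-exponentially); got {self.n}"
            )
        n = self.n
        self._full_mask = (1 << n) - 1
        # node_on[i][b0,...,b_{n-1}] = P(node i up at t+1 | past bits b)
        shape = (2,) * n
        self._node_p = [
            (
                np.ascontiguousarray(
                    1.0 - tpm.probabilities[:, i].reshape(shape, order="F")
                ),
                np.ascontiguousarray(
                    tpm.probabilities[:, i].reshape(shape, order="F")
                ),
            )
            for i in range(n)
        ]
        self._ones = np.ones((1,) * n)
        # subset tables: tuple <-> mask, shapes, drop-axes per kept mask
        self._tuple_of = [
            tuple(k for k in range(n) if (mask >> k) & 1)
            for mask in range(1 << n)
        ]
        self._mask_of = {t: m for m, t in enumerate(self._tuple_of)}
        self._shape_of = [
            tuple(2 if (mask >> k) & 1 else 1 for k in range(n))
            for mask in range(1 << n)
        ]
        self._drop_of = [
            tuple(k for k in range(n) if not (mask >> k) & 1)
            for mask in range(1 << n)
        ]
        self._bit_off_of = []
        for mask in range(1 << n):
            k = bin(mask).count("1")
            codes = np.arange(2**k)
            B = (
                ((codes[:, None] >> np.arange(k)[None, :]) & 1) == 0
            ).astype(float)
            self._bit_off_of.append(B)
        self._uniform_of = []
        for mask in range(1 << n):
            u = np.ascontiguousarray(
                np.broadcast_to(self._ones, self._shape_of[mask])
            ) / 2 ** bin(mask).count("1")
            u.flags.writeable = False
            self._uniform_of.append(u)
        # caches
        self._factor: dict = {}
        self._cause_rep: dict = {}
        self._cause_flat: dict = {}
        self._effect_rep: dict = {}
        self._effect_single: dict = {}
        self._mip: dict = {}
        self._purview_ok: dict = {}
        self._mice: dict = {}
        self._concept_dist: dict = {}
        self._expand_cache: dict = {}
        self._phi_cache: dict[int, PhiResult] = {}
        self._plans: dict = {}

    # -- repertoires ------------------------------------------------------

    def _cause_factor(self, m, bit, keep_mask):
        """Node m's likelihood of its current state, marginalized onto the
        kept past nodes."""
        key = (m, bit, keep_mask)
        hit = self._factor.get(key)
        if hit is None:
            t = self._node_p[m][bit]
            hit = t.mean(axis=self._drop_of[keep_mask], keepdims=True)
            hit.flags.writeable = False
            self._factor[key] = hit
        return hit

    def cause_rep_array(self, mechanism, mbits, purview, cut=_NULL_CUT):
        """Multilinear cause repertoire of a mechanism-state over a purview.

        ``mbits`` holds the mechanism nodes' state bits at their absolute
        positions (other bits are ignored).
        """
        if not purview:
            return self._ones
        fm, tm = cut
        m_mask = self._mask_of[mechanism]
        z_mask = self._mask_of[purview]
        mbits &= m_mask
        key = (m_mask, mbits, z_mask, fm & z_mask, tm & m_mask)
        hit = self._cause_rep.get(key)
        if hit is not None:
            return hit
        if not mechanism:
            out = self._uniform_of[z_mask]
            self._cause_rep[key] = out
            return out
        else:
            joint = None
            for m in mechanism:
                sev = fm if (tm >> m) & 1 else 0
                f = self._cause_factor(m, (mbits >> m) & 1, z_mask & ~sev)
                joint = f if joint is None else joint * f
            total = joint.sum()
            if total > 0:
                joint = joint / total
            out = np.broadcast_to(joint, self._shape_of[z_mask])
            # renormalize in case broadcasting replicated the mass
            out = out / out.sum() if total > 0 else np.array(out)
        out = np.ascontiguousarray(out)
        out.flags.writeable = False
        self._cause_rep[key] = out
        return out

    def effect_single_on(self, j, mechanism, mbits, cut=_NULL_CUT):
        """P(node j up at t+1 | mechanism clamped, everything else noised)."""
        fm, tm = cut
        sev = fm if (tm >> j) & 1 else 0
        cond_mask = self._mask_of[mechanism] & ~sev
        key = (j, cond_mask, mbits & cond_mask)
        hit = self._effect_single.get(key)
        if hit is None:
            t = self._node_p[j][1]
            idx = [slice(None)] * self.n
            for m in self._tuple_of[cond_mask]:
                idx[m] = (mbits >> m) & 1
            hit = float(t[tuple(idx)].mean())
            self._effect_single[key] = hit
        return hit

    def effect_rep_array(self, mechanism, mbits, purview, cut=_NULL_CUT):
        """Multilinear effect repertoire (a product of per-node Bernoullis)."""
        if not purview:
            return self._ones
        fm, tm = cut
        m_mask = self._mask_of[mechanism]
        z_mask = self._mask_of[purview]
        mbits &= m_mask
        key = (m_mask, mbits, z_mask, fm & m_mask, tm & z_mask)
        hit = self._effect_rep.get(key)
        if hit is not None:
            return hit
        out = np.ones(self._shape_of[z_mask])
        for j in purview:
            p = self.effect_single_on(j, mechanism, mbits, cut)
            shape = [1] * self.n
            shape[j] = 2
            out = out * np.array([1.0 - p, p]).reshape(shape)
        out.flags.writeable = False
        self._effect_rep[key] = out
        return out

    def repertoire(self, direction, mechanism, mbits, purview, cut=_NULL_CUT):
        if direction == CAUSE:
            return self.cause_rep_array(mechanism, mbits, purview, cut)
        return self.effect_rep_array(mechanism, mbits, purview, cut)

    # -- mechanism-level MIP ---------------------------------------------

    def _mip_plan(self, mechanism, purview):
        """Precomputed index structure over the partition list of a
        mechanism/purview pair, shared by every state, cut and direction."""
        key = (mechanism, purview)
        plan = self._plans.get(key)
        if plan is not None:
            return plan
        partitions = _mip_bipartitions(mechanism, purview)
        part_index: dict = {}
        parts_list: list = []  # (mm, mm_mask, zz, zz_mask)
        mech_index: dict = {}
        mechs_list: list = []  # (mm, mm_mask)
        P = len(partitions)
        pairs = np.empty((P, 2), dtype=np.int64)
        pmech = np.empty((P, 2), dtype=np.int64)
        zpos = {j: t for t, j in enumerate(purview)}
        in_first = np.zeros((P, len(purview)), dtype=bool)
        for p, ((m1, z1), (m2, z2)) in enumerate(partitions):
            for s, (mm, zz) in enumerate(((m1, z1), (m2, z2))):
                k = part_index.get((mm, zz))
                if k is None:
                    k = len(parts_list)
                    part_index[(mm, zz)] = k
                    parts_list.append(
                        (mm, self._mask_of[mm], zz, self._mask_of[zz])
                    )
                pairs[p, s] = k
                mk = mech_index.get(mm)
                if mk is None:
                    mk = len(mechs_list)
                    mech_index[mm] = mk
                    mechs_list.append(mm)
                pmech[p, s] = mk
            for j in z1:
                in_first[p, zpos[j]] = True
        plan = (partitions, parts_list, pairs, mechs_list, pmech, in_first)
        self._plans[key] = plan
        return plan

    def cause_rep_flat(self, mm, mm_mask, mbits, zz, zz_mask, full_mask, cut):
        """Cause repertoire flattened (little-endian) over the full purview.

        The cache key packs the five masks into one integer (masks fit in
        ``n <= 5`` bits), which keeps this innermost lookup cheap."""
        fm, tm = cut
        b = self.n
        key = (
            mm_mask
            | ((mbits & mm_mask) << b)
            | (zz_mask << (2 * b))
            | (full_mask << (3 * b))
            | ((fm & zz_mask) << (4 * b))
            | ((tm & mm_mask) << (5 * b))
        )
        hit = self._cause_flat.get(key)
        if hit is None:
            hit = np.ravel(
                np.broadcast_to(
                    self.cause_rep_array(mm, mbits, zz, cut),
                    self._shape_of[full_mask],
                ),
                order="F",
            )
            hit.flags.writeable = False
            self._cause_flat[key] = hit
        return hit

    def find_mip(self, direction, mechanism, mbits, purview, cut=_NULL_CUT):
        """phi of the minimum-information partition of (mechanism, purview).

        Returns ``(phi, partition, repertoire_array)``; the partition is
        ``((M1, Z1), (M2, Z2))`` or ``None`` when no partition was needed.
        """
        if not purview:
            return 0.0, None, None
        fm, tm = cut
        m_mask = self._mask_of[mechanism]
        z_mask = self._mask_of[purview]
        mbits &= m_mask
        if direction == CAUSE:
            sig = (fm & z_mask, tm & m_mask)
        else:
            sig = (fm & m_mask, tm & z_mask)
        key = (direction, m_mask, mbits, z_mask, sig)
        hit = self._mip.get(key)
        if hit is not None:
            return hit
        whole = self.repertoire(direction, mechanism, mbits, purview, cut)
        result = self._search_mip(
            direction, mechanism, mbits, purview, z_mask, cut, whole
        )
        self._mip[key] = result
        return result

    def _search_mip(self, direction, mechanism, mbits, purview, z_mask, cut, whole):
        partitions, parts_list, pairs, mechs_list, pmech, in_first = (
            self._mip_plan(mechanism, purview)
        )

        if direction == EFFECT:
            # Effect repertoires factorize over purview nodes, so the EMD of
            # a partition is a per-node sum of Bernoulli differences: node j
            # assigned to part (Mi, Zi) contributes |P(j on | M) -
            # P(j on | Mi)|.  No repertoires need materializing.
            q_whole = np.array(
                [
                    self.effect_single_on(j, mechanism, mbits, cut)
                    for j in purview
                ]
            )
            D = np.empty((len(mechs_list), len(purview)))
            for k, mm in enumerate(mechs_list):
                D[k] = [self.effect_single_on(j, mm, mbits, cut) for j in purview]
            D = np.abs(D - q_whole[None, :])
            costs = np.where(in_first, D[pmech[:, 0]], D[pmech[:, 1]]).sum(1)
            phis = np.round(costs, PRECISION)
            best = int(np.argmin(phis))  # first minimum, as in the reference
            return float(phis[best]), partitions[best], whole

        if not whole.any():
            # state unreachable given this mechanism: defined as reducible
            return 0.0, None, whole

        # cause direction: EMD is the expensive step.  TV = L1/2 is a lower
        # bound on the Hamming EMD (distinct states are at distance >= 1), so
        # candidates are processed in order of that bound and the search stops
        # once the bound exceeds the best distance found; duplicated
        # partitioned repertoires are evaluated once.
        nz = len(purview)
        R = np.empty((len(parts_list), 2**nz))
        for k, (mm, mm_mask, zz, zz_mask) in enumerate(parts_list):
            R[k] = self.cause_rep_flat(
                mm, mm_mask, mbits, zz, zz_mask, z_mask, cut
            )
        products = R[pairs[:, 0]] * R[pairs[:, 1]]
        whole_flat = np.ravel(whole, order="F")
        diffs = products - whole_flat[None, :]
        # two lower bounds for the Hamming EMD: total variation (nearest
        # distinct states are 1 apart) and the summed per-node marginal
        # shifts (each unit of Hamming distance moves one node's marginal)
        lbs = 0.5 * np.abs(diffs).sum(1)
        marg = np.abs(diffs @ self._bit_off_of[z_mask]).sum(1)
        np.maximum(lbs, marg, out=lbs)
        order = np.argsort(lbs, kind="stable")
        best_phi, best_part = np.inf, None
        seen: dict = {}
        for p in order:
            if _round(lbs[p]) > best_phi:
                break
            kb = products[p].tobytes()
            phi = seen.get(kb)
            if phi is None:
                phi = _round(hamming_emd_diff(diffs[p], nz))
                seen[kb] = phi
            if phi == 0.0:
                return 0.0, partitions[p], whole
            if phi < best_phi:
                best_phi, best_part = phi, partitions[p]
        return best_phi, best_part, whole

    # -- purview filtering and MICE --------------------------------------

    def _cut_cm(self, cut):
        fm, tm = cut
        cm = np.ones((self.n, self.n))
        if fm and tm:
            cm[np.ix_(self._tuple_of[fm], self._tuple_of[tm])] = 0.0
        return cm

    def purview_passes(self, direction, mechanism, purview, cut=_NULL_CUT):
        fm, tm = cut
        m_mask = self._mask_of[mechanism]
        z_mask = self._mask_of[purview]
        if direction == CAUSE:
            sig = (fm & z_mask, tm & m_mask)
        else:
            sig = (fm & m_mask, tm & z_mask)
        key = (direction, m_mask, z_mask, sig)
        hit = self._purview_ok.get(key)
        if hit is None:
            cm = self._cut_cm(cut)
            if direction == CAUSE:
                rows, cols = purview, mechanism
            else:
                rows, cols = mechanism, purview
            hit = not _block_reducible(cm, rows, cols)
            self._purview_ok[key] = hit
        return hit

    def find_mice(self, direction, mechanism, mbits, cut=_NULL_CUT):
        """Maximally irreducible cause or effect of a mechanism-state.

        Maximizes phi over purviews; ties prefer the larger purview, then the
        earlier purview in subset order (the reference toolbox's ordering).
        """
        fm, tm = cut
        m_mask = self._mask_of[mechanism]
        mbits &= m_mask
        if direction == CAUSE:
            sig = (fm, tm & m_mask)
        else:
            sig = (fm & m_mask, tm)
        if not (sig[0] and sig[1]):
            sig = (0, 0)
        key = (direction, m_mask, mbits, sig)
        hit = self._mice.get(key)
        if hit is not None:
            return hit

        # NOTE: a cut can *raise* a purview's MIP distance (the partitioned
        # repertoires are noised too), so the intact system's per-purview phi
        # values are not upper bounds and cannot prune this search.
        best = None  # (phi, len(purview)) ordering key
        best_val = (0.0, (), None, None)
        for purview in _powerset(range(self.n), nonempty=True):
            if not self.purview_passes(direction, mechanism, purview, cut):
                continue
            phi, part, rep = self.find_mip(
                direction, mechanism, mbits, purview, cut
            )
            okey = (phi, len(purview))
            if best is None or okey > best:
                best = okey
                best_val = (phi, purview, rep, part)
        self._mice[key] = best_val
        return best_val

    def mice_damaged_by_cut(self, direction, m_mask, purview, cut):
        """Whether a cut could alter a maximally irreducible cause/effect:
        it splits the mechanism or severs purview-mechanism connections."""
        fm, tm = cut
        if (fm & m_mask) and (tm & m_mask):
            return True
        z_mask = self._mask_of[purview]
        if direction == CAUSE:
            return bool(fm & z_mask) and bool(tm & m_mask)
        return bool(fm & m_mask) and bool(tm & z_mask)

    # -- concepts and cause-effect structures ----------------------------

    def concept(self, mechanism, mbits, cut=_NULL_CUT):
        """The concept of a mechanism-state: its irreducible cause and effect.

        For a cut system, a maximally irreducible cause/effect already found
        for the intact system is reused when the cut cannot affect it (it
        does not split the mechanism nor sever the purview-mechanism
        connections) -- the reference toolbox's cache-inheritance rule.
        """
        m_mask = self._mask_of[mechanism]
        mbits &= m_mask
        sides = {}
        for direction in (CAUSE, EFFECT):
            reused = None
            if cut != _NULL_CUT:
                parent = self._mice.get((direction, m_mask, mbits, (0, 0)))
                if (
                    parent is not None
                    and parent[0] > 0
                    and not self.mice_damaged_by_cut(
                        direction, m_mask, parent[1], cut
                    )
                ):
                    reused = parent
            sides[direction] = (
                reused
                if reused is not None
                else self.find_mice(direction, mechanism, mbits, cut)
            )
        return sides[CAUSE], sides[EFFECT]

    def ces(self, state_code, cut=_NULL_CUT, mechanisms=None):
        """Concepts with phi > 0, as internal tuples keyed by mechanism."""
        if mechanisms is None:
            mechanisms = _powerset(range(self.n), nonempty=True)
        out = {}
        for mechanism in mechanisms:
            cause, effect = self.concept(mechanism, state_code, cut)
            phi = min(cause[0], effect[0])
            if phi > 0:
                out[mechanism] = (cause, effect, phi)
        return out

    # -- CES distance (the generalized concept-space EMD) -----------------

    def _expand(self, direction, rep, purview, new_purview, cut):
        """Distribute a repertoire over a larger purview, filling the new
        nodes with the system's unconstrained repertoire.

        Memoized by the repertoire's identity: repertoires live in the
        engine caches, so ``id()`` is stable for the engine's lifetime."""
        if len(new_purview) == len(purview):
            return rep  # nothing to fill in
        key = (direction, id(rep), purview, new_purview, cut)
        hit = self._expand_cache.get(key)
        if hit is not None:
            return hit
        extra = tuple(k for k in new_purview if k not in purview)
        if direction == CAUSE:
            uc = self._uniform_of[self._mask_of[extra]]
        else:
            uc = self.effect_rep_array((), 0, extra, cut)
        out = rep * uc
        total = out.sum()
        out = out / total if total > 0 else out
        self._expand_cache[key] = out
        return out

    def concept_distance(self, mech1, entry1, cut1, mech2, entry2, cut2):
        """Ground distance between two concepts: summed EMDs of their cause
        and effect repertoires expanded over the union purviews."""
        # repertoire arrays are interned in the engine caches, so their
        # identities key the pair distance
        key = (mech1, id(entry1[0][2]), id(entry1[1][2]), cut1,
               mech2, id(entry2[0][2]), id(entry2[1][2]), cut2)
        hit = self._concept_dist.get(key)
        if hit is not None:
            return hit
        total = 0.0
        for direction, idx in ((CAUSE, 0), (EFFECT, 1)):
            side1, side2 = entry1[idx], entry2[idx]
            union = tuple(sorted(set(side1[1]) | set(side2[1])))
            r1 = self._expand(direction, side1[2], side1[1], union, cut1)
            r2 = self._expand(direction, side2[2], side2[1], union, cut2)
            diff = np.ravel(
                np.broadcast_to(r1, self._shape_of[self._mask_of[union]])
                - r2,
                order="F",
            )
            total += hamming_emd_diff(diff, len(union))
        self._concept_dist[key] = total
        return total

    def _null_entry(self):
        """The null concept: unconstrained cause and effect over nothing."""
        side = (0.0, (), self._ones, None)
        return (side, side, 0.0)

    def _emd_eq(self, e1, e2):
        """Concept identity for the CES distance (phi, repertoires)."""
        if e1[2] != e2[2]:
            return False
        for idx in (0, 1):
            r1, r2 = e1[idx][2], e2[idx][2]
            if r1 is r2:
                continue
            if r1.shape != r2.shape or not np.array_equal(r1, r2):
                return False
        return True

    def ces_distance(self, ces1, cut1, ces2, cut2):
        """Distance between two cause-effect structures.

        If concepts only disappear between the structures, each lost
        concept's phi is transported to the null concept; otherwise the
        generalized EMD over concept space is solved exactly.
        """
        only1 = [
            (m, e)
            for m, e in ces1.items()
            if not any(
                m == m2 and self._emd_eq(e, e2) for m2, e2 in ces2.items()
            )
        ]
        only2 = [
            (m, e)
            for m, e in ces2.items()
            if not any(
                m == m1 and self._emd_eq(e, e1) for m1, e1 in ces1.items()
            )
        ]
        null = self._null_entry()
        if not only1 or not only2:
            big, cut = (ces1, cut1) if len(ces1) >= len(ces2) else (ces2, cut2)
            small = ces2 if big is ces1 else ces1
            destroyed = [
                (m, e)
                for m, e in big.items()
                if not any(
                    m == m2 and self._emd_eq(e, e2)
                    for m2, e2 in small.items()
                )
            ]
            dist = sum(
                e[2] * self.concept_distance(m, e, cut, (), null, cut)
                for m, e in destroyed
            )
            return _round(dist)

        n1, n2 = len(only1), len(only2)
        distances = np.array(
            [
                [
                    self.concept_distance(m1, e1, cut1, m2, e2, cut2)
                    for m2, e2 in only2
                ]
                for m1, e1 in only1
            ]
        )
        to_null = np.array(
            [
                self.concept_distance(m, e, cut, (), null, cut)
                for part, cut in ((only1, cut1), (only2, cut2))
                for m, e in part
            ]
        )
        size = n1 + n2 + 1
        C = np.full((size, size), distances.max() + 1.0)
        C[:n1, n1:-1] = distances
        C[n1:-1, :n1] = distances.T
        C[-1, :-1] = to_null
        C[:-1, -1] = to_null
        C[-1, -1] = 0.0
        d1 = np.array([e[2] for _, e in only1] + [0.0] * n2 + [0.0])
        d2 = np.array([0.0] * n1 + [e[2] for _, e in only2] + [0.0])
        balance = d1.sum() - d2.sum()
        # whichever structure has less total phi absorbs the difference at
        # the null concept, so both signatures carry equal mass
        if balance >= 0:
            d2[-1] = balance
        else:
            d1[-1] = -balance
        return _round(transport_cost(d1, d2, C))

    # -- big Phi ----------------------------------------------------------

    def big_phi(self, state_code: int) -> PhiResult:
        # The field-free Ising kernel is symmetric under a global spin flip
        # (P(i up | s) = P(i down | ~s) holds exactly, entry for entry), so
        # Phi of a state equals Phi of its complement and the two share a
        # cache slot.
        canon = min(state_code, state_code ^ self._full_mask)
        hit = self._phi_cache.get(canon)
        if hit is not None:
            return PhiResult(
                phi=hit.phi,
                system_mip=hit.system_mip,
                state_code=state_code,
                temperature=hit.temperature,
                n_concepts=hit.n_concepts,
                from_cache=True,
            )
        result = self._compute_big_phi(canon)
        self._phi_cache[canon] = result
        if canon != state_code:
            result = PhiResult(
                phi=result.phi,
                system_mip=result.system_mip,
                state_code=state_code,
                temperature=result.temperature,
                n_concepts=result.n_concepts,
            )
        return result

    def _compute_big_phi(self, state_code: int) -> PhiResult:
        n = self.n

        def done(phi, mip, ncc):
            return PhiResult(
                phi=phi,
                system_mip=mip,
                state_code=state_code,
                temperature=self.tpm.temperature,
                n_concepts=ncc,
            )

        if n == 1:
            return done(0.0, None, 0)

        whole_ces = self.ces(state_code)
        if not whole_ces:
            return done(0.0, None, 0)

        best_phi, best_cut = np.inf, None
        for frm, to in _directed_bipartitions(tuple(range(n)), nontrivial=True):
            cut = (self._mask_of[frm], self._mask_of[to])
            split = [
                m
                for m in _powerset(range(n), nonempty=True)
                if (cut[0] & self._mask_of[m]) and (cut[1] & self._mask_of[m])
            ]
            mechanisms = sorted(
                set(whole_ces) | set(split), key=lambda m: (len(m), m)
            )
            cut_ces = self.ces(state_code, cut, mechanisms)
            d = self.ces_distance(whole_ces, _NULL_CUT, cut_ces, cut)
            if d == 0.0:
                return done(0.0, (frm, to), len(whole_ces))
            if d < best_phi:
                best_phi, best_cut = d, (frm, to)
        return done(best_phi, best_cut, len(whole_ces))


# ---------------------------------------------------------------------------
# module-level API with engine registry

_engines: dict[bytes, PhiEngine] = {}


def _engine(tpm: StateByNodeTPM) -> PhiEngine:
    key = tpm.probabilities.tobytes()
    eng = _engines.get(key)
    if eng is None:
        eng = PhiEngine(tpm)
        _engines[key] = eng
    return eng


def clear_caches() -> None:
    """Drop all per-TPM engines (frees sweep memory)."""
    _engines.clear()


def _state_to_code(state, n):
    if isinstance(state, (int, np.integer)):
        return int(state)
    return spins_to_code(np.asarray(state))


def _as_repertoire(rep_array, purview):
    # size-2 axes are in node order, so a Fortran-order ravel of the squeezed
    # array is the little-endian flattening over the purview
    flat = np.ravel(np.squeeze(rep_array), order="F")
    return Repertoire(purview=purview, distribution=flat.copy())


def cause_repertoire(
    tpm: StateByNodeTPM, state, mechanism, purview
) -> Repertoire:
    """Distribution over past purview states implied by the mechanism's
    current state (maximum-entropy prior over unconstrained nodes)."""
    code = _state_to_code(state, tpm.n_nodes)
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    eng = _engine(tpm)
    arr = eng.cause_rep_array(mechanism, code, purview)
    return _as_repertoire(arr, purview)


def effect_repertoire(
    tpm: StateByNodeTPM, state, mechanism, purview
) -> Repertoire:
    """Distribution over next-step purview states given the mechanism's
    current state (factorized over purview nodes)."""
    code = _state_to_code(state, tpm.n_nodes)
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    eng = _engine(tpm)
    arr = eng.effect_rep_array(mechanism, code, purview)
    return _as_repertoire(arr, purview)


def repertoire_emd(p: Repertoire, q: Repertoire) -> float:
    """Exact earth-mover distance between two repertoires over the same
    purview, with Hamming ground metric between purview states."""
    if p.purview != q.purview:
        raise ValueError("repertoires must share a purview")
    k = len(p.purview)
    shape = (2,) * k if k else (1,)
    return hamming_emd(
        p.distribution.reshape(shape, order="F"),
        q.distribution.reshape(shape, order="F"),
    )


@dataclass(frozen=True)
class SmallPhiResult:
    phi: float
    purview: tuple[int, ...]
    mip: tuple | None
    repertoire: Repertoire | None


def small_phi(
    tpm: StateByNodeTPM, state, mechanism, direction: str
) -> SmallPhiResult:
    """Irreducibility of one mechanism in one temporal direction: the best
    purview's minimum-information-partition distance."""
    if direction not in (CAUSE, EFFECT):
        raise ValueError(f"direction must be {CAUSE!r} or {EFFECT!r}")
    code = _state_to_code(state, tpm.n_nodes)
    mechanism = tuple(sorted(mechanism))
    eng = _engine(tpm)
    phi, purview, rep, part = eng.find_mice(direction, mechanism, code)
    return SmallPhiResult(
        phi=phi,
        purview=purview,
        mip=part,
        repertoire=None if rep is None else _as_repertoire(rep, purview),
    )


def compute_ces(tpm: StateByNodeTPM, state) -> CauseEffectStructure:
    """All concepts (mechanisms with phi > 0) of the system in this state."""
    code = _state_to_code(state, tpm.n_nodes)
    eng = _engine(tpm)
    raw = eng.ces(code)
    spins = code_to_spins(code, tpm.n_nodes)
    concepts = []
    for mechanism, (cause, effect, phi) in raw.items():
        concepts.append(
            Concept(
                mechanism=mechanism,
                mechanism_state=tuple(int(spins[m]) for m in mechanism),
                cause=MaximallyIrreducible(
                    CAUSE, cause[0], cause[1],
                    None if cause[2] is None
                    else _as_repertoire(cause[2], cause[1]),
                ),
                effect=MaximallyIrreducible(
                    EFFECT, effect[0], effect[1],
                    None if effect[2] is None
                    else _as_repertoire(effect[2], effect[1]),
                ),
            )
        )
    return CauseEffectStructure(state_code=code, concepts=tuple(concepts))


def big_phi(tpm: StateByNodeTPM, state) -> PhiResult:
    """Integrated conceptual information Phi of the whole system in the given
    state: the concept-space distance to the least-destructive unidirectional
    system cut.  Results are cached per (TPM, state)."""
    code = _state_to_code(state, tpm.n_nodes)
    return _engine(tpm).big_phi(code)


def phi_over_trace(
    trace: SimulationTrace,
    tpm: StateByNodeTPM,
    weighting: str = "visit",
    state_weights: np.ndarray | None = None,
) -> PhiTraceResult:
    """Phi summarized over a simulation trace.

    ``weighting='visit'`` evaluates Phi once per distinct visited state and
    averages over iterations (the study protocol).  ``'stationary'``
    weights every state's Phi by an exact stationary law instead: by
    default the stationary distribution of the synchronous kernel (which
    raises when that chain has no unique aperiodic recurrent class, the
    typical case for Metropolis kernels), or by ``state_weights`` -- e.g.
    the Boltzmann distribution when the trace was sampled sequentially.
    """
    eng = _engine(tpm)
    if weighting == "visit":
        codes = np.asarray(trace.state_codes)
        distinct = np.unique(codes)
        phi_by_state = {int(c): eng.big_phi(int(c)).phi for c in distinct}
        series = np.array([phi_by_state[int(c)] for c in codes])
        mean = float(series.mean())
        chi = float(np.mean(series**2) - mean**2)
        n_eval = len(distinct)
        hits = len(codes) - n_eval
    elif weighting == "stationary":
        if state_weights is not None:
            pi = np.asarray(state_weights, dtype=float)
            if pi.shape != (tpm.n_states,) or abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError(
                    "state_weights must be a distribution over all states"
                )
        else:
            pi = stationary_distribution(expand_to_state_by_state(tpm))
        phi_by_state = {
            int(c): eng.big_phi(int(c)).phi for c in range(tpm.n_states)
        }
        vals = np.array([phi_by_state[c] for c in range(tpm.n_states)])
        mean = float(pi @ vals)
        chi = float(pi @ vals**2 - mean**2)
        n_eval = tpm.n_states
        hits = 0
    else:
        raise ValueError("weighting must be 'visit' or 'stationary'")
    return PhiTraceResult(
        phi_mean=mean,
        chi_phi=max(chi, 0.0),
        phi_by_state=phi_by_state,
        weighting=weighting,
        n_evaluations=n_eval,
        n_cache_hits=hits,
    )
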