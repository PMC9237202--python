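"""Channel vector-set provisioning and memory-cost accounting.

Spatially encoding one feature channel requires a triple of hypervectors
``{iM, PFP, NFP}``: an item-memory vector identifying the channel, and a
positive / negative feature-projection vector selected by the feature
value's sign.  Storing three fresh random vectors per channel is expensive
for many-channeled tasks (>200 channels means >600 stored vectors), so this
module implements five provisioning strategies that trade stored vectors
for structure or on-the-fly computation:

``unoptimized``
    Three fresh random vectors per channel (the baseline).
``im_per_modality``
    One shared item-memory bank, sized to the largest modality and reused
    across modalities; a fresh feature-projection pair per channel.
``fp_per_channel``
    The shared item-memory bank plus a single {PFP, NFP} pair per modality,
    shared by all of that modality's channels.
``combinatorial``
    A minimal bank of ``v`` random vectors from which channel triples are
    enumerated such that every bound pair {iM, FP} is used at most once;
    the capacity of a bank is given by :func:`tfc`.
``rule90``
    A single stored random seed vector; every other vector is generated on
    demand by iterating the rule-90 elementary cellular automaton, whose
    update is the XOR of each cell's two cyclic neighbours.  Only the
    per-modality projection pairs and the seed are kept.
``hybrid``
    Bursts of ``bank_size`` vectors generated by the rule-90 chain and
    consumed combinatorially; when a bank's pairing capacity is exhausted
    the chain is continued to burst-generate the next bank.

All strategies are deterministic given ``(layout, dim, seed)``: training
and inference must see bit-identical channel vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .hv_core import Hypervector, bind, permute, random_hypervector

__all__ = [
    "ModalityConfig",
    "DatasetLayout",
    "ChannelVectorSet",
    "ProvisionedMemory",
    "Rule90Chain",
    "CapacityExceededError",
    "DegenerateSeedError",
    "STRATEGIES",
    "rule90_step",
    "rule90_chain",
    "tfc",
    "min_bank_size",
    "allocate_combinatorial",
    "provision",
    "storage_count",
    "request_rate",
]

STRATEGIES = (
    "unoptimized",
    "im_per_modality",
    "fp_per_channel",
    "combinatorial",
    "rule90",
    "hybrid",
)


class CapacityExceededError(ValueError):
    """A vector bank's combinatorial pairing capacity cannot cover the request."""


class DegenerateSeedError(ValueError):
    """A constant (all-0 or all-1) seed is a fixed point / degenerate orbit of rule 90."""


@dataclass(frozen=True)
class ModalityConfig:
    """One sensor modality: a name and its number of feature channels."""

    name: str
    n_channels: int

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"modality {self.name!r} needs >= 1 channel")


@dataclass(frozen=True)
class DatasetLayout:
    """Ordered modality list mapping flat channel indices to modalities.

    The order is significant: it drives the deterministic assignment of
    vectors to channels in every provisioning strategy.
    """

    modalities: Tuple[ModalityConfig, ...]

    def __init__(self, modalities: Sequence[ModalityConfig]):
        object.__setattr__(self, "modalities", tuple(modalities))
        if not self.modalities:
            raise ValueError("layout needs at least one modality")

    @property
    def total_channels(self) -> int:
        return sum(m.n_channels for m in self.modalities)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def max_modality_channels(self) -> int:
        return max(m.n_channels for m in self.modalities)

    def channel_slices(self) -> List[slice]:
        """Flat-index slice of each modality, in layout order."""
        out, start = [], 0
        for m in self.modalities:
            out.append(slice(start, start + m.n_channels))
            start += m.n_channels
        return out

    def to_dict(self) -> List[Dict]:
        return [{"name": m.name, "n_channels": m.n_channels} for m in self.modalities]

    @classmethod
    def from_dict(cls, entries: Sequence[Dict]) -> "DatasetLayout":
        return cls([ModalityConfig(e["name"], int(e["n_channels"])) for e in entries])


@dataclass(frozen=True)
class ChannelVectorSet:
    """The {iM, PFP, NFP} hypervector triple assigned to one feature channel."""

    iM: Hypervector
    PFP: Hypervector
    NFP: Hypervector


# ---------------------------------------------------------------------------
# Rule-90 cellular automaton
# ---------------------------------------------------------------------------

def rule90_step(hv: Hypervector) -> Hypervector:
    """One update of the rule-90 elementary cellular automaton.

    Each cell becomes the XOR of its two cyclic neighbours, which for a
    whole vector is the XOR of its one-step right and left rotations::

        out[i] = hv[(i-1) mod D] ^ hv[(i+1) mod D]
    """
    hv = np.asarray(hv, dtype=np.uint8)
    if hv.shape[-1] < 3:
        raise ValueError("rule 90 needs dimension >= 3")
    return bind(permute(hv, +1), permute(hv, -1))


def _is_constant(hv: np.ndarray) -> bool:
    return bool(np.all(hv == hv[0]))


def rule90_chain(seed_vector: Hypervector, count: int) -> List[Hypervector]:
    """Iterate rule 90 ``count`` times from a seed, returning every state.

    Element 0 is ``rule90_step(seed_vector)``; element ``n`` is the step
    applied to element ``n-1``.  Constant seeds are rejected: all-zero is a
    fixed point of rule 90 and all-one collapses to it in one step, so
    neither can serve as a pseudo-random generator seed.
    """
    seed_vector = np.asarray(seed_vector, dtype=np.uint8)
    if _is_constant(seed_vector):
        raise DegenerateSeedError(
            "constant seed vector is degenerate under rule 90"
        )
    if count < 1:
        raise ValueError("count must be >= 1")
    out = []
    state = seed_vector
    for _ in range(count):
        state = rule90_step(state)
        out.append(state)
    return out


@dataclass
class Rule90Chain:
    """Resumable rule-90 generator: stores the seed and the latest state.

    The hardware reading is that only the most recently generated vector is
    kept locally as the next step's input; replaying from the seed
    reproduces the whole sequence, which is what makes regenerated item
    vectors identical across encoding passes.
    """

    seed_vector: Hypervector
    last_state: Hypervector = field(init=False)
    steps_taken: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.seed_vector = np.asarray(self.seed_vector, dtype=np.uint8)
        if _is_constant(self.seed_vector):
            raise DegenerateSeedError(
                "constant seed vector is degenerate under rule 90"
            )
        self.last_state = self.seed_vector

    def next(self) -> Hypervector:
        self.last_state = rule90_step(self.last_state)
        self.steps_taken += 1
        if _is_constant(self.last_state):
            # Rule 90 is linear over GF(2); on rings whose size is a power
            # of two the update matrix is nilpotent and every orbit hits
            # all-zero within D/2 steps. Dimensions with an odd factor
            # (10,000 included) never collapse this way.
            raise DegenerateSeedError(
                f"rule-90 orbit collapsed to a constant state after "
                f"{self.steps_taken} steps (dimension {self.last_state.size}); "
                "use a dimension that is not a power of two"
            )
        return self.last_state

    def take(self, count: int) -> List[Hypervector]:
        return [self.next() for _ in range(count)]

    def reset(self) -> None:
        self.last_state = self.seed_vector
        self.steps_taken = 0


# ---------------------------------------------------------------------------
# Combinatorial pairing capacity
# ---------------------------------------------------------------------------

def tfc(v: int) -> int:
    """Total feature channels encodable from a bank of ``v`` vectors.

    Under the combinatorial-pairs scheme each channel consumes one iM
    vector and a fresh pair of projection vectors, and every unordered
    {iM, FP} pair may be used at most once across all channels.  Looping
    each bank vector over sequential pairs of its successors gives

        TFC(v) = sum_{n=1}^{v-2} floor((v - n) / 2)

    which grows quadratically in ``v``.
    """
    if v < 3:
        raise ValueError(f"a vector bank needs at least 3 vectors, got {v}")
    return sum((v - n) // 2 for n in range(1, v - 1))


def min_bank_size(n_channels: int) -> int:
    """Smallest bank size ``v >= 3`` whose :func:`tfc` capacity covers ``n_channels``."""
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    v = 3
    while tfc(v) < n_channels:
        v += 1
    return v


def _combinatorial_indices(v: int) -> List[Tuple[int, int, int]]:
    """Canonical (iM, PFP, NFP) bank-index triples, run to exhaustion.

    For each bank index ``n`` (ascending), the partners are consumed as
    sequential pairs ``(n+1, n+2), (n+3, n+4), ...`` while both exist.
    Every unordered {iM, partner} pair appears at most once overall, and the
    number of emitted triples equals ``tfc(v)``.
    """
    out = []
    for n in range(v - 2):
        p = n + 1
        while p + 1 < v:
            out.append((n, p, p + 1))
            p += 2
    return out


def allocate_combinatorial(
    bank: Sequence[Hypervector], n_channels: int
) -> List[ChannelVectorSet]:
    """Assign {iM, PFP, NFP} triples to channels from a shared vector bank.

    Emission is deterministic (see :func:`_combinatorial_indices`); exactly
    the first ``n_channels`` triples are returned.
    """
    v = len(bank)
    if v < 3 or tfc(v) < n_channels:
        raise CapacityExceededError(
            f"bank of {v} vectors covers {tfc(v) if v >= 3 else 0} channels, "
            f"need {n_channels}"
        )
    triples = _combinatorial_indices(v)[:n_channels]
    return [ChannelVectorSet(bank[i], bank[j], bank[k]) for i, j, k in triples]


# ---------------------------------------------------------------------------
# Provisioned memory
# ---------------------------------------------------------------------------

class ProvisionedMemory:
    """Strategy-specific supplier of per-channel vector sets plus cost stats.

    ``channel_set(i)`` is identical on every call and across encoding
    passes; strategies that generate vectors on the fly (rule90, hybrid)
    restart their chain deterministically from the stored seed, so the
    cached sets equal what any replay would produce (:meth:`regenerate`
    rebuilds them from scratch for verification).
    """

    def __init__(
        self,
        strategy: str,
        layout: DatasetLayout,
        dim: int,
        seed: int,
        bank_size: Optional[int] = None,
    ):
        if strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {strategy!r}; expected one of {STRATEGIES}"
            )
        if dim < 3:
            raise ValueError("dimension must be >= 3")
        self.strategy = strategy
        self.layout = layout
        self.dim = dim
        self.seed = seed
        if strategy == "hybrid" and bank_size is None:
            # Default to the rule-90 storage budget: same stored vectors,
            # fewer generation requests.
            bank_size = 2 * layout.n_modalities + 1
        if strategy == "hybrid" and bank_size < 3:
            raise ValueError("hybrid bank_size must be >= 3")
        self.bank_size = bank_size if strategy == "hybrid" else (
            min_bank_size(layout.total_channels) if strategy == "combinatorial" else None
        )
        self.rule90_seed_vector: Optional[Hypervector] = None
        self._sets = self._build()
        self._proj_cache: Optional[Tuple[np.ndarray, np.ndarray]] = None

    # -- construction ------------------------------------------------------

    def _draw_seed_vector(self, rng: np.random.Generator) -> Hypervector:
        while True:
            hv = random_hypervector(self.dim, rng)
            if not _is_constant(hv):
                return hv

    def _build(self) -> List[ChannelVectorSet]:
        rng = np.random.default_rng(self.seed)
        layout, dim = self.layout, self.dim
        C = layout.total_channels
        builder = {
            "unoptimized": self._build_unoptimized,
            "im_per_modality": self._build_im_per_modality,
            "fp_per_channel": self._build_fp_per_channel,
            "combinatorial": self._build_combinatorial,
            "rule90": self._build_rule90,
            "hybrid": self._build_hybrid,
        }[self.strategy]
        sets = builder(rng)
        assert len(sets) == C
        return sets

    def _build_unoptimized(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        return [
            ChannelVectorSet(
                random_hypervector(self.dim, rng),
                random_hypervector(self.dim, rng),
                random_hypervector(self.dim, rng),
            )
            for _ in range(self.layout.total_channels)
        ]

    def _im_bank(self, rng: np.random.Generator) -> List[Hypervector]:
        return [
            random_hypervector(self.dim, rng)
            for _ in range(self.layout.max_modality_channels)
        ]

    def _build_im_per_modality(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        bank = self._im_bank(rng)
        sets = []
        for mod in self.layout.modalities:
            for j in range(mod.n_channels):
                sets.append(
                    ChannelVectorSet(
                        bank[j],
                        random_hypervector(self.dim, rng),
                        random_hypervector(self.dim, rng),
                    )
                )
        return sets

    def _build_fp_per_channel(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        bank = self._im_bank(rng)
        sets = []
        for mod in self.layout.modalities:
            pfp = random_hypervector(self.dim, rng)
            nfp = random_hypervector(self.dim, rng)
            for j in range(mod.n_channels):
                sets.append(ChannelVectorSet(bank[j], pfp, nfp))
        return sets

    def _build_combinatorial(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        bank = [random_hypervector(self.dim, rng) for _ in range(self.bank_size)]
        return allocate_combinatorial(bank, self.layout.total_channels)

    def _build_rule90(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        self.rule90_seed_vector = self._draw_seed_vector(rng)
        chain = Rule90Chain(self.rule90_seed_vector)
        # First 2m outputs: one {PFP, NFP} pair per modality, layout order.
        fp_pairs = [(chain.next(), chain.next()) for _ in self.layout.modalities]
        sets = []
        for mod, (pfp, nfp) in zip(self.layout.modalities, fp_pairs):
            for _ in range(mod.n_channels):
                sets.append(ChannelVectorSet(chain.next(), pfp, nfp))
        return sets

    def _build_hybrid(self, rng: np.random.Generator) -> List[ChannelVectorSet]:
        self.rule90_seed_vector = self._draw_seed_vector(rng)
        chain = Rule90Chain(self.rule90_seed_vector)
        b = self.bank_size
        per_burst = tfc(b)
        sets: List[ChannelVectorSet] = []
        remaining = self.layout.total_channels
        while remaining > 0:
            # Burst-generate the next bank by continuing the chain; banks are
            # disjoint vector sets, so cross-bank pair collisions cannot occur.
            bank = chain.take(b)
            n = min(per_burst, remaining)
            sets.extend(allocate_combinatorial(bank, n))
            remaining -= n
        return sets

    # -- access ------------------------------------------------------------

    def channel_set(self, i: int) -> ChannelVectorSet:
        """The {iM, PFP, NFP} triple for flat channel index ``i``."""
        return self._sets[i]

    def channel_sets(self) -> List[ChannelVectorSet]:
        return list(self._sets)

    def projection_matrices(self) -> Tuple[np.ndarray, np.ndarray]:
        """Stacked per-channel spatial encodings, one row per channel.

        Returns ``(pos, neg)`` of shape ``(C, D)`` where ``pos[i] = iM_i ^
        PFP_i`` and ``neg[i] = iM_i ^ NFP_i`` — the only two hypervectors a
        channel can contribute, selected by its feature value's sign.
        """
        if self._proj_cache is None:
            pos = np.stack([bind(s.iM, s.PFP) for s in self._sets])
            neg = np.stack([bind(s.iM, s.NFP) for s in self._sets])
            self._proj_cache = (pos, neg)
        return self._proj_cache

    def regenerate(self) -> "ProvisionedMemory":
        """Rebuild the memory from its stored seed (a fresh encoding pass)."""
        return ProvisionedMemory(
            self.strategy, self.layout, self.dim, self.seed, self.bank_size
        )

    # -- cost statistics ----------------------------------------------------

    @property
    def stored_vector_count(self) -> int:
        return storage_count(self.strategy, self.layout, self.bank_size)

    @property
    def request_rate(self) -> float:
        return request_rate(self.strategy, self.bank_size)


def provision(
    strategy: str,
    layout: DatasetLayout,
    dim: int,
    seed: int,
    bank_size: Optional[int] = None,
) -> ProvisionedMemory:
    """Build a :class:`ProvisionedMemory` for one strategy, layout and seed."""
    return ProvisionedMemory(strategy, layout, dim, seed, bank_size)


def storage_count(
    strategy: str, layout: DatasetLayout, bank_size: Optional[int] = None
) -> int:
    """Number of hypervectors a strategy must keep in storage.

    Closed forms, with ``C`` total channels, ``m`` modalities and ``K_max``
    the largest modality's channel count:

    ==================  =========================
    unoptimized         ``3 * C``
    im_per_modality     ``K_max + 2 * C``
    fp_per_channel      ``K_max + 2 * m``
    combinatorial       ``min_bank_size(C)``
    rule90              ``2 * m + 1``
    hybrid              ``bank_size + 2 * m + 1``
    ==================  =========================
    """
    C = layout.total_channels
    m = layout.n_modalities
    k_max = layout.max_modality_channels
    if strategy == "unoptimized":
        return 3 * C
    if strategy == "im_per_modality":
        return k_max + 2 * C
    if strategy == "fp_per_channel":
        return k_max + 2 * m
    if strategy == "combinatorial":
        return min_bank_size(C)
    if strategy == "rule90":
        return 2 * m + 1
    if strategy == "hybrid":
        if bank_size is None:
            bank_size = 2 * m + 1
        return bank_size + 2 * m + 1
    raise ValueError(f"unknown strategy {strategy!r}")


def request_rate(strategy: str, bank_size: Optional[int] = None) -> float:
    """Steady-state vector-generation requests per channel encoded.

    Pure rule-90 generation requests (and generates) one vector per feature
    channel, a rate of 1.  The hybrid scheme bursts ``bank_size`` vectors
    and then encodes ``tfc(bank_size)`` channels from them, a steady-state
    rate of ``bank_size / tfc(bank_size)``.  Storage-only strategies never
    generate, rate 0.
    """
    if strategy == "rule90":
        return 1.0
    if strategy == "hybrid":
        if bank_size is None or bank_size < 3:
            raise ValueError("hybrid request rate needs bank_size >= 3")
        return bank_size / tfc(bank_size)
    if strategy in STRATEGIES:
        return 0.0
    raise ValueError(f"unknown strategy {strategy!r}")
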