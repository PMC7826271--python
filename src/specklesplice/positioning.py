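"""Interface positioning along an annotated transcript.

Generalises the two-state reporter model to a whole transcript: a transcript
sitting at a speckle/nucleoplasm interface is described by an ensemble of
*interface states*, each placing one contiguous stretch of the transcript in
the speckle phase and the rest in the nucleoplasm.  The energy of a state is
the sum of per-k-mer transfer energies over the windows fully contained in
its speckle-side stretch; windows straddling an interface contribute to
neither side.  Energies are reported relative to the all-nucleoplasm
reference state, and occupancies follow the Boltzmann distribution over the
enumerated ensemble.

The default ensemble has one state per annotated splice site — with the
adjacent exon segment immersed in the speckle, so the splice site sits at
the interface — optionally augmented with two bulk states (whole transcript
in one phase) and, for exon definition, a "U" state with a single internal
exon in the speckle and both flanking introns outside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .kmer import KmerEnergyTable, canonicalize, encode, window_codes
from .thermo import ThermoConfig

EXON = "exon"
INTRON = "intron"
FIVE_PRIME_SS = "5ss"
THREE_PRIME_SS = "3ss"


@dataclass(frozen=True)
class Segment:
    """Half-open [start, end) exon or intron segment."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (EXON, INTRON):
            raise ValueError(f"segment label must be 'exon' or 'intron', got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpliceSite:
    """Boundary between an exon and an intron.

    ``position`` is the 0-based coordinate of the boundary; ``kind`` is
    ``'5ss'`` for exon->intron and ``'3ss'`` for intron->exon;
    ``exon_segment_index`` points at the exon-side segment in the
    transcript's segment list.
    """

    position: int
    kind: str
    exon_segment_index: int


class TranscriptAnnotation:
    """A transcript sequence with an exon/intron segmentation.

    Segments must tile ``[0, len(sequence))`` without gaps or overlaps and
    alternate between exon and intron; every internal boundary is a splice
    site (5'SS at exon->intron, 3'SS at intron->exon).
    """

    def __init__(self, sequence: str, segments, name: str = "transcript") -> None:
        self.name = str(name)
        self.sequence = canonicalize(sequence)
        segs = [s if isinstance(s, Segment) else Segment(*s) for s in segments]
        if not segs:
            raise ValueError("at least one segment is required")
        if segs[0].start != 0:
            raise ValueError(f"first segment must start at 0, starts at {segs[0].start}")
        if segs[-1].end != len(self.sequence):
            raise ValueError(
                f"segments end at {segs[-1].end} but sequence has length {len(self.sequence)}"
            )
        for prev, cur in zip(segs, segs[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"segments must tile the sequence without gaps or overlaps; "
                    f"[{prev.start},{prev.end}) is followed by [{cur.start},{cur.end})"
                )
            if cur.label == prev.label:
                raise ValueError("adjacent segments must alternate exon/intron labels")
        self.segments: list[Segment] = segs
        self._codes = encode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __repr__(self) -> str:
        pat = "-".join(s.label[0] for s in self.segments)
        return f"TranscriptAnnotation({self.name!r}, {len(self)} nt, {pat})"

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def splice_sites(self) -> list[SpliceSite]:
        sites = []
        for i, (left, right) in enumerate(zip(self.segments, self.segments[1:])):
            if left.label == EXON:
                sites.append(SpliceSite(left.end, FIVE_PRIME_SS, i))
            else:
                sites.append(SpliceSite(left.end, THREE_PRIME_SS, i + 1))
        return sites

    @property
    def exon_indices(self) -> list[int]:
        """Segment-list indices of the exon segments, in transcript order."""
        return [i for i, s in enumerate(self.segments) if s.label == EXON]


class _EnergyProfile:
    """Prefix sums of per-window energies for O(1) span queries."""

    def __init__(self, codes: np.ndarray, table: KmerEnergyTable) -> None:
        self.k = table.k
        self.length = len(codes)
        if self.length >= self.k:
            w = table.lookup(window_codes(codes, self.k))
        else:
            w = np.zeros(0)
        self.window_energies = w
        self.cum = np.concatenate([[0.0], np.cumsum(w)])

    def span_energy(self, start: int, end: int) -> float:
        """Sum of energies of windows fully inside [start, end)."""
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"span [{start}, {end}) outside sequence of length {self.length}")
        if end - start < self.k:
            return 0.0
        return float(self.cum[end - self.k + 1] - self.cum[start])


@dataclass
class InterfaceState:
    """One configuration of the transcript relative to the speckle.

    ``speckle_start``/``speckle_end`` delimit the half-open stretch inside the
    speckle (an empty interval for the all-nucleoplasm state).  ``cut`` is the
    interface coordinate for splice-site states and ``None`` for bulk states;
    the U state has both interfaces at the speckle interval's ends.
    """

    label: str
    kind: str  # "site" | "bulk" | "exon_u"
    speckle_start: int
    speckle_end: int
    energy: float
    cut: int | None = None
    orientation: str | None = None  # side of the cut in the speckle
    weight: float = field(default=float("nan"))


class InterfaceStateSet:
    """Boltzmann ensemble over enumerated interface states.

    Normalised weights are attached to each state; ``log_partition`` is the
    log-sum-exp of ``-energy/kT``.
    """

    def __init__(self, states: list[InterfaceState], config: ThermoConfig | None = None):
        if not states:
            raise ValueError("state set must be non-empty")
        self.config = config or ThermoConfig()
        self.states = states
        log_w = np.array([-s.energy / self.config.kT for s in states])
        self.log_partition = float(logsumexp(log_w))
        weights = np.exp(log_w - self.log_partition)
        for state, w in zip(states, weights):
            state.weight = float(w)

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.states])

    def weight(self, label: str) -> float:
        for state in self.states:
            if state.label == label:
                return state.weight
        raise KeyError(label)

    def site_occupancy(self) -> dict[int, float]:
        """Boltzmann occupancy of each splice-site state, keyed by cut position."""
        return {s.cut: s.weight for s in self.states if s.kind == "site"}


def cut_energy(
    transcript: TranscriptAnnotation,
    cut: int,
    orientation: str,
    table: KmerEnergyTable,
) -> float:
    """Energy of the state with one side of ``cut`` immersed in the speckle.

    ``orientation`` names the speckle side: ``"5prime"`` puts ``[0, cut)``
    inside the speckle, ``"3prime"`` puts ``[cut, len)``.  Windows straddling
    the cut are excluded (their contributions cancel between states).
    """
    if not (0 <= cut <= len(transcript)):
        raise ValueError(f"cut {cut} outside sequence of length {len(transcript)}")
    prof = _EnergyProfile(transcript.codes, table)
    if orientation == "5prime":
        return prof.span_energy(0, cut)
    if orientation == "3prime":
        return prof.span_energy(cut, len(transcript))
    raise ValueError(f"orientation must be '5prime' or '3prime', got {orientation!r}")


def interface_landscape(
    transcript: TranscriptAnnotation,
    table: KmerEnergyTable,
    orientation: str = "5prime",
) -> np.ndarray:
    """Per-cut-point energy profile over boundary positions 0..len.

    Entry ``c`` equals ``cut_energy(transcript, c, orientation, table)``;
    computed incrementally from prefix sums in O(len) window evaluations.
    """
    prof = _EnergyProfile(transcript.codes, table)
    L, k = prof.length, prof.k
    landscape = np.zeros(L + 1)
    if L < k:
        return landscape
    if orientation == "5prime":
        landscape[k:] = prof.cum[1 : L - k + 2]
    elif orientation == "3prime":
        total = prof.cum[L - k + 1]
        landscape[: L - k + 1] = total - prof.cum[: L - k + 1]
    else:
        raise ValueError(f"orientation must be '5prime' or '3prime', got {orientation!r}")
    return landscape


def _site_states(
    transcript: TranscriptAnnotation, prof: _EnergyProfile
) -> list[InterfaceState]:
    sites = transcript.splice_sites
    if not sites:
        raise ValueError("transcript has no annotated splice sites")
    states = []
    for site in sites:
        seg = transcript.segments[site.exon_segment_index]
        states.append(
            InterfaceState(
                label=f"{site.kind}@{site.position}",
                kind="site",
                speckle_start=seg.start,
                speckle_end=seg.end,
                energy=prof.span_energy(seg.start, seg.end),
                cut=site.position,
                orientation="5prime" if seg.end == site.position else "3prime",
            )
        )
    return states


def _bulk_states(
    transcript: TranscriptAnnotation, prof: _EnergyProfile
) -> list[InterfaceState]:
    L = len(transcript)
    return [
        InterfaceState("all_speckle", "bulk", 0, L, prof.span_energy(0, L)),
        InterfaceState("all_nucleoplasm", "bulk", 0, 0, 0.0),
    ]


def splice_site_occupancy(
    transcript: TranscriptAnnotation,
    table: KmerEnergyTable,
    config: ThermoConfig | None = None,
    include_bulk_states: bool = False,
) -> InterfaceStateSet:
    """Boltzmann ensemble with one interface state per annotated splice site.

    Each splice-site state immerses the adjacent exon segment in the speckle,
    so the splice site itself sits at the interface.  With
    ``include_bulk_states`` two additional states place the whole transcript
    in a single phase; these give intronic sequence a voice in the ensemble
    (intron windows are in no splice-site state's speckle stretch).
    Occupancies are the normalised weights, available via
    :meth:`InterfaceStateSet.site_occupancy`.
    """
    config = config or ThermoConfig(k=table.k)
    prof = _EnergyProfile(transcript.codes, table)
    states = _site_states(transcript, prof)
    if include_bulk_states:
        states.extend(_bulk_states(transcript, prof))
    return InterfaceStateSet(states, config)


def exon_definition_state_set(
    transcript: TranscriptAnnotation,
    exon_index: int,
    table: KmerEnergyTable,
    config: ThermoConfig | None = None,
    include_bulk_states: bool = False,
) -> InterfaceStateSet:
    """Splice-site ensemble augmented with the exon-definition U state.

    The U state places the interior of exon ``exon_index`` (index among exon
    segments, 0-based) in the speckle with both flanking introns outside, so
    both of the exon's splice sites lie on the interface simultaneously.
    """
    config = config or ThermoConfig(k=table.k)
    exon_positions = transcript.exon_indices
    if not (0 <= exon_index < len(exon_positions)):
        raise ValueError(f"exon_index {exon_index} out of range (have {len(exon_positions)} exons)")
    seg_idx = exon_positions[exon_index]
    if seg_idx == 0 or seg_idx == len(transcript.segments) - 1:
        raise ValueError(
            f"exon {exon_index} is terminal (no flanking intron on one side); "
            "exon definition requires an internal exon"
        )
    seg = transcript.segments[seg_idx]
    prof = _EnergyProfile(transcript.codes, table)
    states = _site_states(transcript, prof)
    if include_bulk_states:
        states.extend(_bulk_states(transcript, prof))
    states.append(
        InterfaceState(
            label=f"U@exon{exon_index}",
            kind="exon_u",
            speckle_start=seg.start,
            speckle_end=seg.end,
            energy=prof.span_energy(seg.start, seg.end),
        )
    )
    return InterfaceStateSet(states, config)


def exon_definition_probability(
    transcript: TranscriptAnnotation,
    exon_index: int,
    table: KmerEnergyTable,
    config: ThermoConfig | None = None,
    include_bulk_states: bool = False,
) -> float:
    """Boltzmann weight of the exon-definition U state of one internal exon."""
    ensemble = exon_definition_state_set(
        transcript, exon_index, table, config, include_bulk_states
    )
    return ensemble.weight(f"U@exon{exon_index}")


def competing_site_ensemble(
    sequence: str,
    cuts,
    table: KmerEnergyTable,
    config: ThermoConfig | None = None,
    speckle_side: str = "3prime",
) -> InterfaceStateSet:
    """Ensemble of candidate interface positions on a plain sequence.

    One state per cut point, with the speckle occupying the given side of the
    cut.  With ``speckle_side="3prime"`` and cuts at the two competing splice
    sites of a reporter, this reduces exactly to the two-state usage model:
    the state cut at the upstream site has the random region inside the
    speckle.
    """
    config = config or ThermoConfig(k=table.k)
    codes = encode(sequence)
    prof = _EnergyProfile(codes, table)
    L = prof.length
    states = []
    for cut in cuts:
        cut = int(cut)
        if not (0 <= cut <= L):
            raise ValueError(f"cut {cut} outside sequence of length {L}")
        if speckle_side == "3prime":
            start, end = cut, L
        elif speckle_side == "5prime":
            start, end = 0, cut
        else:
            raise ValueError(f"speckle_side must be '5prime' or '3prime', got {speckle_side!r}")
        states.append(
            InterfaceState(
                label=f"cut@{cut}",
                kind="site",
                speckle_start=start,
                speckle_end=end,
                energy=prof.span_energy(start, end),
                cut=cut,
                orientation=speckle_side,
            )
        )
    return InterfaceStateSet(states, config)
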