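"""Deterministic discrete-event simulation of ribosome traffic on one transcript.

A ribosome is represented by its active-site codon index (1-based). It dwells
exactly ``tau_k`` seconds at codon ``k`` and then attempts to advance; the
move succeeds only if the exclusion zone downstream is clear, i.e. the next
ribosome's active site is at least ``footprint`` codons ahead of the target
codon. A fresh ribosome attempts to attach at codon 1 every
``initiation_interval`` seconds, subject to the same exclusion rule. After
dwelling on the final codon the ribosome releases its protein and vacates
immediately (all non-elongation time is booked to initiation).

Two collision policies are supported: ``halt`` stops the run at the first
blocked advance or blocked entry and reports the implicated active sites
(the behaviour an interactive viewer wants); ``queue`` lets blocked
ribosomes wait and move the instant space frees, discarding blocked
initiation attempts (the behaviour a throughput calculation wants). Up to
the first blocked event the two policies produce identical event logs.

Simultaneous events are resolved downstream-first: at a given instant the
leading ribosome moves before its followers, so a follower whose dwell has
already elapsed advances at the very instant space frees. This fixed
tie-break makes every run exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .errors import CollisionError, InvalidCDSError, InvalidEditError, InvalidProfileError
from .genetics import STOP_CODONS, codons_of, require_sense_codon

#: Default exclusion-zone width: a ribosome covers about 10 codons.
DEFAULT_FOOTPRINT = 10

#: Relative time resolution: events closer than this are simultaneous.
#: Absorbs float accumulation drift between independent dwell-time sums so
#: that knife-edge configurations resolve by the downstream-first rule
#: rather than by rounding noise.
TIME_RTOL = 1e-9


def validate_cds(cds: Sequence[str] | str) -> list[str]:
    """Normalize a CDS to a list of sense codons; reject internal stops."""
    codons = codons_of(cds) if isinstance(cds, str) else [c for c in cds]
    if not codons:
        raise InvalidCDSError("empty coding sequence")
    for i, c in enumerate(codons, start=1):
        if c.upper().replace("U", "T") in STOP_CODONS:
            raise InvalidCDSError(f"stop codon {c} at codon position {i}")
        codons[i - 1] = require_sense_codon(c)
    return codons


@dataclass(frozen=True)
class SimConfig:
    """Run parameters for one transcript.

    ``initiation_interval`` is the translation initiation time I in seconds;
    ``tau_profile`` holds per-codon dwell times in seconds and must match the
    CDS length. ``horizon`` (seconds) and ``max_proteins`` bound the run;
    when both are ``None`` the run lasts 10x the total elongation time or
    100 completed proteins, whichever comes first.
    """

    initiation_interval: float
    tau_profile: tuple[float, ...]
    footprint: int = DEFAULT_FOOTPRINT
    collision_mode: str = "halt"
    horizon: float | None = None
    max_proteins: int | None = None

    def __post_init__(self):
        if self.initiation_interval <= 0:
            raise InvalidProfileError("initiation_interval must be > 0")
        if self.footprint < 1:
            raise InvalidProfileError("footprint must be >= 1 codon")
        if self.collision_mode not in ("halt", "queue"):
            raise InvalidProfileError(
                f"collision_mode must be 'halt' or 'queue', got {self.collision_mode!r}"
            )
        object.__setattr__(self, "tau_profile", tuple(float(t) for t in self.tau_profile))
        if not self.tau_profile or any(t <= 0 for t in self.tau_profile):
            raise InvalidProfileError("tau_profile must be non-empty with all entries > 0")


@dataclass(frozen=True)
class SimEvent:
    time: float
    ribosome: int
    action: str  # initiate | advance | terminate | blocked
    codon: int   # 1-based active-site codon (1 for a blocked entry)


@dataclass
class SimulationResult:
    events: list[SimEvent]
    proteins_completed: int
    collision: tuple[float, list[int]] | None
    mean_occupancy: float
    initiations: int
    entry_blocked: int
    end_time: float
    final_positions: list[int] = field(default_factory=list)

    @property
    def queued(self) -> bool:
        """True if any blocked advance or blocked entry occurred."""
        return self.collision is not None or any(e.action == "blocked" for e in self.events)


@dataclass
class _Ribosome:
    id: int
    pos: int
    dwell_end: float
    blocked: bool = False


def simulate(cds: Sequence[str] | str, config: SimConfig) -> SimulationResult:
    """Run the exclusion-process simulation of one transcript."""
    codons = validate_cds(cds)
    L = len(codons)
    tau = config.tau_profile
    if len(tau) != L:
        raise InvalidProfileError(
            f"tau_profile length {len(tau)} does not match CDS length {L} codons"
        )
    f = config.footprint
    I = config.initiation_interval
    halt = config.collision_mode == "halt"

    total_E = sum(tau)
    horizon = config.horizon
    max_prot = config.max_proteins
    if horizon is None and max_prot is None:
        horizon, max_prot = 10.0 * total_E, 100

    ribs: list[_Ribosome] = []  # ordered front (largest pos) first
    events: list[SimEvent] = []
    next_init = 0.0
    next_id = 0
    proteins = 0
    initiations = 0
    entry_blocked = 0
    collision: tuple[float, list[int]] | None = None
    occ_integral = 0.0
    last_t = 0.0
    end_time = 0.0
    stopped = False

    while not stopped:
        candidates = [r.dwell_end for r in ribs if not r.blocked]
        if horizon is None or next_init <= horizon:
            candidates.append(next_init)
        if not candidates:
            break
        t = min(candidates)
        if horizon is not None and t > horizon:
            break
        occ_integral += len(ribs) * (t - last_t)
        last_t = t
        end_time = t
        cutoff = t + TIME_RTOL * (1.0 + t)

        # --- advances / terminations, downstream-first ---
        survivors: list[_Ribosome] = []
        for rib in ribs:
            if stopped or rib.dwell_end > cutoff:
                survivors.append(rib)
                continue
            if rib.pos == L:
                proteins += 1
                events.append(SimEvent(t, rib.id, "terminate", L))
                if max_prot is not None and proteins >= max_prot:
                    stopped = True
                continue
            leader = survivors[-1] if survivors else None
            if leader is None or leader.pos >= rib.pos + 1 + f:
                rib.pos += 1
                rib.dwell_end = t + tau[rib.pos - 1]
                rib.blocked = False
                events.append(SimEvent(t, rib.id, "advance", rib.pos))
            else:
                if not rib.blocked:
                    rib.blocked = True
                    events.append(SimEvent(t, rib.id, "blocked", rib.pos))
                if halt:
                    collision = (t, [rib.pos, leader.pos])
                    stopped = True
            survivors.append(rib)
        ribs = survivors

        # --- initiation attempt (the most-upstream event) ---
        if not stopped and next_init <= cutoff and (horizon is None or next_init <= horizon):
            rearmost = ribs[-1] if ribs else None
            if rearmost is None or rearmost.pos >= 1 + f:
                ribs.append(_Ribosome(next_id, 1, t + tau[0]))
                events.append(SimEvent(t, next_id, "initiate", 1))
                next_id += 1
                initiations += 1
            else:
                entry_blocked += 1
                events.append(SimEvent(t, next_id, "blocked", 1))
                next_id += 1
                if halt:
                    collision = (t, [1, rearmost.pos])
                    stopped = True
            next_init += I

    if collision is None and not stopped and horizon is not None:
        # run exhausted the time horizon; close the occupancy integral there
        occ_integral += len(ribs) * (horizon - last_t)
        end_time = horizon

    mean_occ = occ_integral / end_time if end_time > 0 else float(len(ribs))
    return SimulationResult(
        events=events,
        proteins_completed=proteins,
        collision=collision,
        mean_occupancy=mean_occ,
        initiations=initiations,
        entry_blocked=entry_blocked,
        end_time=end_time,
        final_positions=[r.pos for r in ribs],
    )


def detect_queuing(cds: Sequence[str] | str, config: SimConfig) -> tuple[bool, int | None]:
    """Whether any ribosome is ever blocked before the horizon, and where first.

    Runs in halt mode regardless of ``config.collision_mode``; deterministic
    for fixed inputs. Returns ``(queued, first_blocked_codon)``.
    """
    res = simulate(cds, replace(config, collision_mode="halt"))
    for e in res.events:
        if e.action == "blocked":
            return True, e.codon
    return False, None


def steady_state_load(cds: Sequence[str] | str, config: SimConfig) -> float:
    """Long-run time-averaged ribosome count on the transcript.

    For a collision-free transcript this converges to E/I as the horizon
    grows (arrival rate 1/I times residence time E). In halt mode a
    collision aborts the run with :class:`CollisionError`.
    """
    res = simulate(cds, config)
    if res.collision is not None:
        raise CollisionError(res.collision[0], res.collision[1])
    return res.mean_occupancy


def mutate_cds(
    cds: Sequence[str] | str, edits: Sequence[tuple[int, str]]
) -> list[str]:
    """Apply point mutations (1-based codon index, replacement codon) purely.

    Replacement codons must be sense codons: an internal stop would truncate
    the reading frame, which is rejected rather than modeled.
    """
    codons = validate_cds(cds)
    out = list(codons)
    for idx, new in edits:
        if not 1 <= idx <= len(out):
            raise InvalidEditError(f"codon index {idx} out of range 1..{len(out)}")
        try:
            out[idx - 1] = require_sense_codon(new)
        except Exception as exc:
            raise InvalidEditError(f"edit at codon {idx}: {exc}") from exc
    return out
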