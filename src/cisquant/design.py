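"""Design of motif-knockout enhancer variants.

The designer destroys target TFBSs with transition substitutions only
(A<->G, C<->T), so purine/pyrimidine identity — and hence length and
spacing — is preserved.  For each target hit it searches mutation plans by
iterative deepening on the number of substitutions (1..k_max), trying the
highest-information-content motif columns first, and accepts the first
plan under which

* no window overlapping the original hit retains a target-motif match at
  the p-value threshold (either strand — a shifted window must not
  survive),
* every protected hit still matches at its exact coordinates and strand
  (unless explicitly allowed as collateral), and
* no new hit of any watched motif appears near the edits.

A full rescan of the finished variant against every watched matrix then
verifies the construct end to end; conflicts that only emerge globally
trigger exclusion of the offending combination and a fresh design cycle.
Infeasible sites are reported together with the protected hits every
otherwise-successful candidate would have destroyed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .motifs import Background, LogOddsMatrix, PWM, information_content, pwm_log_odds
from .scan import MotifHit, ScanConfig, scan_sequence

__all__ = [
    "MotifLibrary",
    "DesignConstraints",
    "MutationPlan",
    "VerificationReport",
    "EnhancerVariant",
    "InfeasibilityRecord",
    "transition",
    "rank_positions",
    "apply_plan",
    "invert_plan",
    "design_site_knockout",
    "verify_variant",
    "design_construct",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def transition(base: str) -> str:
    """The other purine for a purine, the other pyrimidine for a pyrimidine."""
    try:
        return _TRANSITION[base.upper()]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def rank_positions(pwm: PWM, bg: Background | None = None) -> list[int]:
    """Motif columns ordered by decreasing information content.

    The most constrained ('important') columns come first; ties break to
    the leftmost column.  This operationalizes mutating the positions a
    binding logo shows as tallest.
    """
    ic = information_content(pwm)
    return sorted(range(pwm.width), key=lambda j: (-ic[j], j))


@dataclass
class MotifLibrary:
    """The set of matrices in play: counts plus their compiled scoring forms."""

    pwms: dict[str, PWM]
    loms: dict[str, LogOddsMatrix]

    @classmethod
    def build(
        cls,
        pwms: list[PWM],
        bg: Background | None = None,
        pseudocount: float = 0.1,
    ) -> "MotifLibrary":
        bg = bg or Background.uniform()
        loms = {p.motif_id: pwm_log_odds(p, bg, pseudocount) for p in pwms}
        return cls(pwms={p.motif_id: p for p in pwms}, loms=loms)

    def max_width(self, motif_ids=None) -> int:
        ids = motif_ids if motif_ids is not None else list(self.loms)
        return max(self.loms[m].width for m in ids)


@dataclass
class DesignConstraints:
    """What to destroy, what to watch, and what must survive.

    ``allowed_collateral`` lists hit ids (``motif@start-end(strand)``) of
    protected hits whose loss is tolerated — the escape hatch needed when a
    target site and a protected site share core positions.
    """

    target_motif_ids: list[str]
    watch_motif_ids: list[str]
    protected_hits: list[MotifHit] = field(default_factory=list)
    allowed_collateral: list[str] = field(default_factory=list)
    k_max: int = 4

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        allowed = set(self.allowed_collateral)
        for h in self.protected_hits:
            if h.motif_id in self.target_motif_ids and h.hit_id not in allowed:
                raise ValueError(
                    f"protected hit {h.hit_id} is also a target and not allowed collateral"
                )

    @property
    def all_watch_ids(self) -> list[str]:
        seen = dict.fromkeys(list(self.watch_motif_ids) + list(self.target_motif_ids))
        return list(seen)


@dataclass(frozen=True)
class MutationPlan:
    """Transition substitutions (1-based positions) destroying target hits."""

    substitutions: tuple[tuple[int, str, str], ...]
    target_hit_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be unique")
        for pos, ref, alt in self.substitutions:
            if alt != transition(ref):
                raise ValueError(
                    f"substitution {ref}->{alt} at {pos} is not a transition"
                )

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _, _ in self.substitutions)

    def merged(self, other: "MutationPlan") -> "MutationPlan":
        return MutationPlan(
            substitutions=tuple(sorted(self.substitutions + other.substitutions)),
            target_hit_ids=self.target_hit_ids + other.target_hit_ids,
        )


@dataclass(frozen=True)
class InfeasibilityRecord:
    """Why a site could not be knocked out: the conflicting protected hits."""

    target_hit_id: str
    conflicts: tuple[str, ...]
    reason: str

    @property
    def feasible(self) -> bool:
        return False


@dataclass
class VerificationReport:
    """Outcome of rescanning a variant against every watched matrix."""

    lost_target_hits: list[MotifHit]
    surviving_target_hits: list[MotifHit]
    lost_protected_hits: list[MotifHit]
    new_hits: list[MotifHit]
    passed: bool


@dataclass
class EnhancerVariant:
    name: str
    sequence: str
    plan: MutationPlan
    report: VerificationReport


def apply_plan(seq: str, plan: MutationPlan) -> str:
    """Apply substitutions; length is conserved, refs are checked."""
    chars = list(seq)
    for pos, ref, alt in plan.substitutions:
        if not (1 <= pos <= len(seq)):
            raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
        if chars[pos - 1].upper() != ref:
            raise ValueError(
                f"reference mismatch at {pos}: plan says {ref}, sequence has {chars[pos - 1]}"
            )
        chars[pos - 1] = alt
    return "".join(chars)


def invert_plan(plan: MutationPlan) -> MutationPlan:
    """Swap ref/alt; applying a plan then its inverse restores the input."""
    return MutationPlan(
        substitutions=tuple((p, alt, ref) for p, ref, alt in plan.substitutions),
        target_hit_ids=plan.target_hit_ids,
    )


def _scan_region(
    seq: str, loms: list[LogOddsMatrix], bg: Background, cfg: ScanConfig,
    start0: int, end0: int, seq_id: str = "seq",
) -> list[MotifHit]:
    """Scan seq[start0:end0] and shift hits back to full-sequence coordinates."""
    start0 = max(0, start0)
    end0 = min(len(seq), end0)
    sub = seq[start0:end0]
    hits: list[MotifHit] = []
    for lom in loms:
        for h in scan_sequence(sub, lom, bg, cfg, seq_id=seq_id):
            hits.append(
                MotifHit(
                    motif_id=h.motif_id, seq_id=h.seq_id,
                    start=h.start + start0, end=h.end + start0,
                    strand=h.strand, score=h.score, p_value=h.p_value,
                    matched_seq=h.matched_seq,
                )
            )
    return hits


def _hit_columns_to_positions(hit: MotifHit, ncols: int) -> list[int]:
    """Map motif column j to the 1-based sequence position it reads."""
    if hit.strand == "+":
        return [hit.start + j for j in range(ncols)]
    return [hit.end - j for j in range(ncols)]


def design_site_knockout(
    seq: str,
    hit: MotifHit,
    library: MotifLibrary,
    constraints: DesignConstraints,
    bg: Background | None = None,
    cfg: ScanConfig | None = None,
    excluded: set[tuple[tuple[int, str, str], ...]] | None = None,
) -> MutationPlan | InfeasibilityRecord:
    """Find the smallest transition-substitution set destroying one hit.

    Success means no window overlapping the original hit retains a
    target-motif match at the threshold — a shifted or overlapping window
    must not survive.  Candidate positions therefore span the whole
    cluster of overlapping same-motif hits, ranked by column information
    content, and the substitution budget is k_max per cluster hit.
    Iterative deepening on k; within each k, combinations are tried in
    order of decreasing summed information content, ties broken by
    leftmost positions, so the search is fully deterministic.  Returns the
    first plan that kills the site without harming protected hits or
    creating new watched-motif hits near the edits; otherwise an
    :class:`InfeasibilityRecord` naming the protected hits that every
    otherwise-lethal candidate would have destroyed.
    """
    bg = bg or Background.uniform()
    cfg = cfg or ScanConfig()
    excluded = excluded or set()
    if hit.motif_id not in library.loms:
        raise KeyError(f"motif {hit.motif_id} not in library")
    target_lom = library.loms[hit.motif_id]
    pwm = library.pwms[hit.motif_id]
    w = target_lom.width

    # confirm the hit is currently present
    current = _scan_region(seq, [target_lom], bg, cfg, hit.start - 1 - 2 * w, hit.end + 2 * w)
    if hit.key not in {h.key for h in current}:
        raise ValueError(f"{hit.hit_id} is not a current hit of {hit.motif_id}")

    ic = information_content(pwm)
    # overlapping hits of the same motif form one cluster: killing every
    # window that overlaps the focal hit can require edits in a
    # neighboring hit's columns, so the candidate pool spans the cluster
    cluster = [h for h in current if h.start <= hit.end and h.end >= hit.start]
    pos_ic: dict[int, float] = {}
    for ch in cluster:
        for j, p in enumerate(_hit_columns_to_positions(ch, w)):
            if 1 <= p <= len(seq) and (p not in pos_ic or ic[j] > pos_ic[p]):
                pos_ic[p] = float(ic[j])
    pool = sorted(pos_ic, key=lambda p: (-pos_ic[p], p))[:12]
    k_cap = min(constraints.k_max * len(cluster), len(pool))
    watch_loms = [library.loms[m] for m in constraints.all_watch_ids]
    max_w = library.max_width(constraints.all_watch_ids)
    allowed = set(constraints.allowed_collateral)

    def local_window(plan_positions: tuple[int, ...]) -> tuple[int, int]:
        lo = min(min(plan_positions), hit.start) - 1
        hi = max(max(plan_positions), hit.end)
        return (lo - max_w + 1, hi + max_w - 1)

    conflicts: list[str] = []
    saw_lethal = False
    for k in range(1, k_cap + 1):
        combos = sorted(
            itertools.combinations(pool, k),
            key=lambda ps: (-sum(pos_ic[p] for p in ps), tuple(sorted(ps))),
        )
        for ps in combos:
            subs = tuple(
                sorted(
                    (p, seq[p - 1].upper(), transition(seq[p - 1]))
                    for p in ps
                )
            )
            if subs in excluded:
                continue
            plan = MutationPlan(substitutions=subs, target_hit_ids=(hit.hit_id,))
            variant = apply_plan(seq, plan)
            lo, hi = local_window(plan.positions)

            # knockout: no target window overlapping the original hit survives
            var_target = _scan_region(variant, [target_lom], bg, cfg, lo, hi)
            if any(h.start <= hit.end and h.end >= hit.start for h in var_target):
                continue
            saw_lethal = True

            wt_hits = {h.key for h in _scan_region(seq, watch_loms, bg, cfg, lo, hi)}
            var_hits = _scan_region(variant, watch_loms, bg, cfg, lo, hi)
            var_keys = {h.key for h in var_hits}

            destroyed = [
                p.hit_id
                for p in constraints.protected_hits
                if p.key in wt_hits and p.key not in var_keys and p.hit_id not in allowed
            ]
            if destroyed:
                for d in destroyed:
                    if d not in conflicts:
                        conflicts.append(d)
                continue
            new = [
                h for h in var_hits
                if h.key not in wt_hits
                and not (h.motif_id == hit.motif_id and h.start <= hit.end and h.end >= hit.start)
            ]
            if new:
                continue
            return plan

    reason = (
        "every lethal candidate destroys a protected hit"
        if saw_lethal and conflicts
        else f"no transition plan with <= {k_cap} substitutions removes the site"
    )
    return InfeasibilityRecord(
        target_hit_id=hit.hit_id, conflicts=tuple(conflicts), reason=reason
    )


def _scan_all(
    seq: str, library: MotifLibrary, motif_ids: list[str],
    bg: Background, cfg: ScanConfig,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for m in motif_ids:
        hits.extend(scan_sequence(seq, library.loms[m], bg, cfg))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return hits


def verify_variant(
    wildtype: str,
    variant: str,
    library: MotifLibrary,
    constraints: DesignConstraints,
    bg: Background | None = None,
    cfg: ScanConfig | None = None,
) -> VerificationReport:
    """Full rescan of the variant with every watched matrix.

    Hits are matched across the two sequences by (motif, interval, strand);
    substitution-only designs keep coordinates stable, so identity of a hit
    is its exact location.  The report passes iff no target hit survives,
    no new hit of any watched motif appeared, and every lost protected hit
    was explicitly allowed as collateral.
    """
    if len(wildtype) != len(variant):
        raise ValueError("wildtype and variant must be the same length")
    bg = bg or Background.uniform()
    cfg = cfg or ScanConfig()
    watch_ids = constraints.all_watch_ids
    wt_hits = _scan_all(wildtype, library, watch_ids, bg, cfg)
    var_hits = _scan_all(variant, library, watch_ids, bg, cfg)
    wt_keys = {h.key for h in wt_hits}
    var_keys = {h.key for h in var_hits}

    wt_targets = [h for h in wt_hits if h.motif_id in constraints.target_motif_ids]
    lost_target = [h for h in wt_targets if h.key not in var_keys]
    surviving_target = [h for h in wt_targets if h.key in var_keys]
    lost_protected = [p for p in constraints.protected_hits if p.key in wt_keys and p.key not in var_keys]
    new_hits = [h for h in var_hits if h.key not in wt_keys]

    allowed = set(constraints.allowed_collateral)
    passed = (
        not surviving_target
        and not new_hits
        and all(p.hit_id in allowed for p in lost_protected)
    )
    return VerificationReport(
        lost_target_hits=lost_target,
        surviving_target_hits=surviving_target,
        lost_protected_hits=lost_protected,
        new_hits=new_hits,
        passed=passed,
    )


def design_construct(
    seq: str,
    constraints: DesignConstraints,
    library: MotifLibrary,
    bg: Background | None = None,
    cfg: ScanConfig | None = None,
    name: str = "variant",
    max_cycles: int = 12,
) -> EnhancerVariant | InfeasibilityRecord:
    """Knock out every target-motif hit in a sequence, verified end to end.

    Target hits are processed left to right with a rescan after every
    applied plan, so sites created or shifted by earlier edits are caught
    in later cycles.  If the final verification fails, the combination
    responsible for the offending hit is excluded and the whole design is
    restarted; the search is deterministic throughout.
    """
    bg = bg or Background.uniform()
    cfg = cfg or ScanConfig()
    exclusions: dict[str, set[tuple]] = {}

    for _attempt in range(max_cycles):
        current = seq
        plans: list[MutationPlan] = []
        infeasible: InfeasibilityRecord | None = None
        for _cycle in range(max_cycles):
            target_hits = _scan_all(current, library, list(constraints.target_motif_ids), bg, cfg)
            target_hits = [h for h in target_hits if h.hit_id not in set(constraints.allowed_collateral)]
            if not target_hits:
                break
            hit = target_hits[0]
            result = design_site_knockout(
                current, hit, library, constraints, bg, cfg,
                excluded=exclusions.get(hit.hit_id),
            )
            if isinstance(result, InfeasibilityRecord):
                infeasible = result
                break
            current = apply_plan(current, result)
            plans.append(result)
        else:
            return InfeasibilityRecord(
                target_hit_id="<construct>", conflicts=(),
                reason=f"target hits kept reappearing after {max_cycles} cycles",
            )
        if infeasible is not None:
            return infeasible

        combined = MutationPlan(substitutions=(), target_hit_ids=())
        for p in plans:
            combined = combined.merged(p)
        report = verify_variant(seq, current, library, constraints, bg, cfg)
        if report.passed:
            return EnhancerVariant(name=name, sequence=current, plan=combined, report=report)

        # find the plan whose edits sit closest to an offending hit and
        # exclude that combination before restarting
        offending = report.new_hits + [
            p for p in report.lost_protected_hits
            if p.hit_id not in set(constraints.allowed_collateral)
        ]
        if not offending or not plans:
            return InfeasibilityRecord(
                target_hit_id="<construct>", conflicts=tuple(h.hit_id for h in offending),
                reason="verification failed with no excludable plan",
            )
        off = offending[0]
        culprit = min(
            plans,
            key=lambda p: min(
                abs(pos - off.start) + abs(pos - off.end) for pos in p.positions
            ),
        )
        exclusions.setdefault(culprit.target_hit_ids[0], set()).add(culprit.substitutions)
    return InfeasibilityRecord(
        target_hit_id="<construct>", conflicts=(),
        reason=f"no conflict-free design found in {max_cycles} restarts",
    )
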