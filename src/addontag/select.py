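"""Greedy forward selection of add-on tag SNPs.

Three variant sets evolve per region: candidate targets S1 (common but poorly
imputed), candidate add-on tags S2 (common, probe-able, sequenced), and
existing tags S3 (the base array, growing as add-ons are accepted).  Each
target j carries its current coverage s_j = max_{i in S3} I_ij; a candidate
tag k offers delta_jk = I_jk - s_j to each target and is scored by the
efficiency

    e_k = sum_j max(0, delta_jk) / N_k

with N_k its required probe count.  The accepted tag k* minimises the sum of
its efficiency rank and probe-ability rank (rank 1 = best, competition
ranking on ties).

Setting 1 iterates each prioritized region independently until almost no
target improves; Setting 2 runs one global iteration across all regions at a
time under a total probe budget.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import (
    HaplotypePanel,
    ImputationQualityTable,
    InsufficientDataError,
    ProbeInfo,
    ValidationError,
    VariantKey,
    probes_required,
)
from .ld import MIMatrix, pairwise_mi
from .regions import Region

logger = logging.getLogger(__name__)


@dataclass
class TagSets:
    """The three evolving variant sets of one region run."""

    s1: list[VariantKey]  # candidate targets (fixed)
    s2: list[VariantKey]  # candidate add-on tags (shrinks)
    s3: set[VariantKey]  # existing tags (grows)

    def __post_init__(self) -> None:
        if set(self.s2) & self.s3:
            raise ValidationError("S2 and S3 must be disjoint")


@dataclass
class CandidateScore:
    """Scores of one candidate tag against the current selection state."""

    key: VariantKey
    delta: dict[VariantKey, float]
    e_k: float
    n_probes: int
    probeability: float
    rank_e: int | None = None
    rank_p: int | None = None

    @property
    def combined_rank(self) -> int:
        if self.rank_e is None or self.rank_p is None:
            raise ValueError("ranks not assigned")
        return self.rank_e + self.rank_p

    @property
    def n_improved(self) -> int:
        return sum(1 for d in self.delta.values() if d > 0)


@dataclass
class AcceptedTag:
    key: VariantKey
    region_id: str
    setting: int
    order: int
    score: CandidateScore
    n_improved: int


@dataclass
class SelectionResult:
    """Ordered accepted add-on tags with probe accounting."""

    accepted: list[AcceptedTag] = field(default_factory=list)

    @property
    def n_tags(self) -> int:
        return len(self.accepted)

    @property
    def n_probes(self) -> int:
        return sum(a.score.n_probes for a in self.accepted)

    @property
    def keys(self) -> list[VariantKey]:
        return [a.key for a in self.accepted]

    def counts_per_region(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.accepted:
            counts[a.region_id] = counts.get(a.region_id, 0) + 1
        return counts

    def keys_per_region(self) -> dict[str, list[VariantKey]]:
        out: dict[str, list[VariantKey]] = {}
        for a in self.accepted:
            out.setdefault(a.region_id, []).append(a.key)
        return out

    def extend(self, other: "SelectionResult") -> None:
        self.accepted.extend(other.accepted)


def find_candidates(
    panel: HaplotypePanel,
    quality: ImputationQualityTable,
    probes: dict[VariantKey, ProbeInfo],
    array: list[VariantKey],
    region: Region,
    maf_min: float = 0.05,
    quality_max: float = 0.8,
    probeability_min: float = 0.3,
    missingness_max: float = 0.5,
    site_list: set[VariantKey] | None = None,
) -> TagSets:
    """Resolve the S1/S2/S3 sets for one region.

    Variants absent from the quality table are treated as never imputed
    (quality 0) and hence as candidate targets if common.  ``site_list``
    optionally restricts S2 to variants present in a reference panel.
    """
    members = region.members or panel.variants_in(region.chrom, region.start, region.end)
    s3 = {t for t in array if region.contains(t)}
    for t in sorted(s3):
        if t not in panel:
            logger.warning("array tag %s not present in panel; kept in S3", (t,))

    common: list[VariantKey] = []
    for v in members:
        if v not in panel:
            continue
        try:
            if panel.maf(v) > maf_min:
                common.append(v)
        except InsufficientDataError:
            continue

    s1 = [v for v in common if quality.quality(v, default=0.0) < quality_max]
    s2 = [
        v
        for v in common
        if v not in s3
        and panel.missingness(v) < missingness_max
        and v in probes
        and probes[v].probeability > probeability_min
        and (site_list is None or v in site_list)
    ]
    return TagSets(s1=s1, s2=s2, s3=s3)


def _rank_best_first(values: list[float]) -> np.ndarray:
    """Competition ranks with 1 = highest value; ties share the minimal rank."""
    return rankdata([-v for v in values], method="min").astype(int)


def _tiebreak_key(score: CandidateScore) -> tuple:
    # ties on combined rank: higher e_k, then fewer probes, then genomic order
    return (score.combined_rank, -score.e_k, score.n_probes,
            score.key.chrom, score.key.pos, score.key.ref, score.key.alt)


def assign_ranks(scores: list[CandidateScore]) -> None:
    """Assign efficiency and probe-ability ranks over a candidate pool in place."""
    re = _rank_best_first([s.e_k for s in scores])
    rp = _rank_best_first([s.probeability for s in scores])
    for s, a, b in zip(scores, re, rp):
        s.rank_e = int(a)
        s.rank_p = int(b)


class SelectionState:
    """Mutable per-region state of the forward-selection loop."""

    def __init__(
        self,
        region: Region,
        panel: HaplotypePanel | None,
        tagsets: TagSets,
        probes: dict[VariantKey, ProbeInfo],
        mi: MIMatrix | None = None,
    ) -> None:
        self.region = region
        self.panel = panel
        self.tagsets = tagsets
        self.probes = probes
        self.probes_used = 0
        self.iteration = 0
        if mi is not None:
            self.mi: MIMatrix | None = mi
        elif panel is not None:
            cols = list(tagsets.s2) + [t for t in sorted(tagsets.s3) if t in panel]
            self.mi = pairwise_mi(panel, tagsets.s1, cols) if tagsets.s1 and cols else None
        else:
            raise ValidationError("either a panel or a precomputed MI matrix is required")
        self.s: dict[VariantKey, float] = {}
        for j in tagsets.s1:
            best = 0.0
            for t in tagsets.s3:
                val = self._mi(j, t)
                best = max(best, val)
            self.s[j] = best

    def _mi(self, j: VariantKey, k: VariantKey) -> float:
        if self.mi is None or not self.mi.has(j, k):
            return 0.0
        val = self.mi.get(j, k)
        if math.isnan(val):
            logger.debug("missing MI for pair (%s, %s); treated as 0", j, k)
            return 0.0
        return val

    def probe_info(self, k: VariantKey) -> ProbeInfo:
        info = self.probes.get(k)
        if info is not None:
            return info
        return ProbeInfo(probeability=float("nan"), n_probes=probes_required(k))

    def score_candidate(self, k: VariantKey) -> CandidateScore:
        """Score candidate k against the current s_j values."""
        info = self.probe_info(k)
        delta = {j: self._mi(j, k) - self.s[j] for j in self.tagsets.s1}
        gain = sum(max(0.0, d) for d in delta.values())
        return CandidateScore(
            key=k,
            delta=delta,
            e_k=gain / info.n_probes,
            n_probes=info.n_probes,
            probeability=info.probeability,
        )

    def score_all(self, pool: list[VariantKey] | None = None) -> list[CandidateScore]:
        pool = pool if pool is not None else list(self.tagsets.s2)
        return [self.score_candidate(k) for k in pool]

    def accept(self, score: CandidateScore) -> None:
        """Move the scored candidate from S2 to S3 and refresh coverage."""
        k = score.key
        self.tagsets.s2.remove(k)
        self.tagsets.s3.add(k)
        for j in self.tagsets.s1:
            self.s[j] = max(self.s[j], self._mi(j, k))
        self.probes_used += score.n_probes
        self.iteration += 1


def pick_best(scores: list[CandidateScore]) -> CandidateScore | None:
    """Rank a candidate pool and return the rank-sum argmin, or None if no
    candidate improves any target (all e_k = 0)."""
    if not scores:
        return None
    if all(s.e_k == 0.0 for s in scores):
        return None
    assign_ranks(scores)
    return min(scores, key=_tiebreak_key)


def select_next(state: SelectionState) -> AcceptedTag | None:
    """Run one iteration: score S2, pick the rank-sum argmin, accept it."""
    best = pick_best(state.score_all())
    if best is None:
        return None
    state.accept(best)
    return AcceptedTag(
        key=best.key,
        region_id=state.region.id,
        setting=state.region.setting,
        order=state.iteration,
        score=best,
        n_improved=best.n_improved,
    )


def run_setting1(
    states: list[SelectionState], stop_frac: float = 0.005
) -> SelectionResult:
    """Coverage-guaranteeing selection: iterate each region independently
    until the accepted tag improves fewer than ``ceil(stop_frac * |S1|)``
    targets (minimum one)."""
    result = SelectionResult()
    order = 0
    for state in states:
        if not state.tagsets.s1:
            logger.info("region %s: no candidate targets, skipped", state.region.id)
            continue
        threshold = max(1, math.ceil(stop_frac * len(state.tagsets.s1)))
        while True:
            acc = select_next(state)
            if acc is None:
                break
            order += 1
            acc.order = order
            acc.setting = 1
            result.accepted.append(acc)
            if acc.n_improved < threshold:
                break
    return result


def run_setting2(
    states: list[SelectionState],
    probe_budget: int = 5000,
    already_used: int = 0,
) -> SelectionResult:
    """Efficiency-driven global selection under a probe budget.

    Each global iteration takes the best candidate of every region (within-
    region rank sum over candidates that fit the remaining budget and improve
    at least one target), re-ranks those winners globally, and accepts the
    global rank-sum argmin, decrementing the budget by its probe count.
    """
    result = SelectionResult()
    remaining = probe_budget - already_used
    order = 0
    while remaining > 0:
        pool: list[tuple[SelectionState, CandidateScore]] = []
        for state in states:
            feasible = [
                k for k in state.tagsets.s2
                if state.probe_info(k).n_probes <= remaining
            ]
            scores = [s for s in state.score_all(feasible) if s.e_k > 0.0]
            best = pick_best(scores)
            if best is not None:
                pool.append((state, best))
        if not pool:
            break
        globals_ = [sc for _, sc in pool]
        winner = pick_best(globals_)
        if winner is None:
            break
        state = next(st for st, sc in pool if sc is winner)
        state.accept(winner)
        remaining -= winner.n_probes
        order += 1
        result.accepted.append(
            AcceptedTag(
                key=winner.key,
                region_id=state.region.id,
                setting=2,
                order=order,
                score=winner,
                n_improved=winner.n_improved,
            )
        )
    return result


def random_selection(
    regions: list[Region],
    counts_per_region: dict[str, int],
    panel: HaplotypePanel,
    quality: ImputationQualityTable,
    array: list[VariantKey],
    seed: int,
    probes: dict[VariantKey, ProbeInfo] | None = None,
    proposed: dict[str, list[VariantKey]] | None = None,
    maf_min: float = 0.05,
    missingness_max: float = 0.5,
    site_list: set[VariantKey] | None = None,
) -> SelectionResult:
    """Baseline: per region, sample the same number of add-on tags uniformly.

    The candidate pool uses the same criteria as S2 except that no
    probe-ability threshold applies; tags picked by the main approach are
    excluded from the pool but are re-admitted at random when the pool is too
    small to reach the matching count.
    """
    rng = np.random.default_rng(seed)
    proposed = proposed or {}
    result = SelectionResult()
    order = 0
    array_set = set(array)
    for region in regions:
        count = counts_per_region.get(region.id, 0)
        if count == 0:
            continue
        picked_here = proposed.get(region.id, [])
        members = region.members or panel.variants_in(region.chrom, region.start, region.end)
        pool = []
        for v in members:
            if v in array_set or v in picked_here or v not in panel:
                continue
            try:
                if panel.maf(v) <= maf_min:
                    continue
            except InsufficientDataError:
                continue
            if panel.missingness(v) >= missingness_max:
                continue
            if site_list is not None and v not in site_list:
                continue
            pool.append(v)
        pool = sorted(set(pool))
        if not pool and not picked_here:
            raise ValidationError(
                f"region {region.id}: no candidates for random selection"
            )
        if len(pool) >= count:
            chosen = [pool[i] for i in rng.choice(len(pool), size=count, replace=False)]
        else:
            chosen = list(pool)
            topup = sorted(set(picked_here))
            need = min(count - len(chosen), len(topup))
            if need > 0:
                chosen += [topup[i] for i in rng.choice(len(topup), size=need, replace=False)]
            if len(chosen) < count:
                logger.warning(
                    "region %s: only %d of %d random tags available",
                    region.id, len(chosen), count,
                )
        for v in chosen:
            order += 1
            pa = probes[v].probeability if probes and v in probes else float("nan")
            score = CandidateScore(
                key=v, delta={}, e_k=float("nan"),
                n_probes=probes_required(v), probeability=pa,
            )
            result.accepted.append(
                AcceptedTag(key=v, region_id=region.id, setting=region.setting,
                            order=order, score=score, n_improved=0)
            )
    return result


def haplogroup_addons(
    parents: dict[str, str | None],
    markers: dict[str, list[VariantKey]],
    cohort_calls: dict[str, str],
    array: list[VariantKey],
    depth: int = 2,
) -> set[VariantKey]:
    """Marker SNPs to add for haplogroup resolution.

    For every haplogroup observed in the cohort, the markers of that node and
    of all nodes up to ``depth`` branch points below it are included, minus
    markers already on the array.
    """
    nodes = set(parents) | set(markers)
    children: dict[str, list[str]] = {}
    for node, parent in parents.items():
        if parent is not None:
            children.setdefault(parent, []).append(node)
    chosen: set[VariantKey] = set()
    for sample, call in cohort_calls.items():
        if call not in nodes:
            raise ValidationError(
                f"sample {sample}: haplogroup {call!r} absent from the tree"
            )
        frontier = [call]
        for _ in range(depth + 1):
            next_frontier: list[str] = []
            for node in frontier:
                chosen.update(markers.get(node, []))
                next_frontier.extend(children.get(node, []))
            frontier = next_frontier
    return chosen - set(array)
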