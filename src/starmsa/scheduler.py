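"""Two-pool workload partitioning and parallel pairwise execution.

A short pre-computation aligns the same small sample on both worker pools
and measures durations t1 and t2; the capability ratio R = t1/t2 then
splits the n pairwise tasks as n1 = n/(R+1) to pool 1 and the rest to
pool 2.  Workers share no mutable state and results are collected in
dataset order, so the final MSA is bit-identical to a serial run.

The published design pairs a CPU pool with a GPU; here both pools are
configurable CPU worker pools so the ratio logic is testable anywhere.
"""

from __future__ import annotations

import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Sequence as TypingSequence

from starmsa.seqio import Dataset, Sequence
from starmsa.pairwise import (
    DEFAULT_SCORING,
    PairwiseAlignment,
    ScoringScheme,
    kband_align,
    nw_align,
)


class WorkerError(RuntimeError):
    """A pool worker failed; the message names the failing sequence."""


@dataclass(frozen=True)
class WorkloadPartition:
    """Measured pre-computation and the resulting task split."""

    ratio: float
    n1: int
    n2: int
    t1: float | None = None
    t2: float | None = None


class WorkerPool:
    """Thread-backed pool mapping a pure function over tasks in order.

    ``workers <= 1`` degrades to a serial loop.  Because the mapped
    function is pure, the output is independent of scheduling.
    """

    def __init__(self, workers: int, name: str = "pool"):
        if workers < 0:
            raise ValueError("worker count must be >= 0")
        self.workers = workers
        self.name = name

    @property
    def available(self) -> bool:
        return self.workers > 0

    def map(self, fn: Callable, items: TypingSequence) -> list:
        if not items:
            return []
        if self.workers <= 1:
            return [fn(item) for item in items]
        with ThreadPoolExecutor(max_workers=self.workers) as ex:
            return list(ex.map(fn, items))


def partition(n: int, ratio: float) -> tuple[int, int]:
    """Split n tasks as (n1, n2) with n1 = round(n / (ratio + 1)).

    Rounding is round-half-even; n1 + n2 == n always holds and
    |n1 - n/(R+1)| <= 1.
    """
    if n < 0:
        raise ValueError("task count must be >= 0")
    if ratio <= 0:
        raise ValueError("capability ratio must be > 0")
    n1 = int(round(n / (ratio + 1.0)))
    return n1, n - n1


def default_sample_size(n: int) -> int:
    """Pre-computation sample size: min(max(32, 1% of n), n // 2)."""
    return min(max(32, n // 100), n // 2)


def estimate_ratio(
    sample: TypingSequence,
    pool1: WorkerPool,
    pool2: WorkerPool,
    task_fn: Callable,
    timer: Callable[[WorkerPool, TypingSequence], float] | None = None,
) -> tuple[float, float, float]:
    """Measure (t1, t2, R): both pools run the same sample, R = t1/t2.

    *timer* overrides the wall-clock measurement (for deterministic tests);
    it receives (pool, sample) and returns a duration.  If a pool is
    unavailable the ratio falls back to the static worker-count ratio.
    """
    if not sample:
        raise ValueError("pre-computation sample must be non-empty")
    if not (pool1.available and pool2.available):
        if pool1.workers == 0:
            raise ValueError("pool 1 must have at least one worker")
        ratio = pool2.workers / pool1.workers if pool2.workers else 0.0
        return 0.0, 0.0, ratio

    if timer is None:

        def timer(pool: WorkerPool, tasks: TypingSequence) -> float:
            start = time.perf_counter()
            pool.map(task_fn, tasks)
            return time.perf_counter() - start

    t1 = timer(pool1, sample)
    t2 = timer(pool2, sample)
    if t2 <= 0:
        raise ValueError("pool 2 sample duration must be positive")
    return t1, t2, t1 / t2


def plan_partition(
    n: int,
    pool1: WorkerPool,
    pool2: WorkerPool | None,
    sample: TypingSequence,
    task_fn: Callable,
    ratio: float | None = None,
    timer: Callable | None = None,
) -> WorkloadPartition:
    """Decide the (n1, n2) split, measuring R unless overridden."""
    if pool2 is None or not pool2.available:
        return WorkloadPartition(ratio=0.0, n1=n, n2=0)
    if ratio is not None:
        n1, n2 = partition(n, ratio)
        return WorkloadPartition(ratio=ratio, n1=n1, n2=n2)
    t1, t2, measured = estimate_ratio(sample, pool1, pool2, task_fn, timer)
    if measured <= 0:
        return WorkloadPartition(ratio=0.0, n1=n, n2=0, t1=t1, t2=t2)
    n1, n2 = partition(n, measured)
    return WorkloadPartition(ratio=measured, n1=n1, n2=n2, t1=t1, t2=t2)


def run_corun(
    data: Dataset,
    center_index: int,
    s: ScoringScheme = DEFAULT_SCORING,
    pool1: WorkerPool | None = None,
    pool2: WorkerPool | None = None,
    ratio: float | None = None,
    banded: bool = False,
    k: int | None = None,
    align_fn: Callable[[str, Sequence], PairwiseAlignment] | None = None,
    timer: Callable | None = None,
    return_partition: bool = False,
):
    """Align the center against every other sequence across two pools.

    Returns the pairwise alignments in dataset order (center excluded),
    bit-identical to a serial run.  ``align_fn(center, record)`` may be
    injected for testing; worker failures abort with the failing id.
    With ``return_partition=True`` returns (alignments, WorkloadPartition).
    """
    if data.n < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if not 0 <= center_index < data.n:
        raise ValueError(f"center index {center_index} out of range")
    pool1 = pool1 or WorkerPool(1, "pool1")
    center = data[center_index].residues

    if align_fn is None:
        if banded:
            def align_fn(c: str, rec: Sequence) -> PairwiseAlignment:
                return kband_align(c, rec.residues, s, k)
        else:
            def align_fn(c: str, rec: Sequence) -> PairwiseAlignment:
                return nw_align(c, rec.residues, s)

    def task(rec: Sequence) -> PairwiseAlignment:
        try:
            return align_fn(center, rec)
        except Exception as exc:
            raise WorkerError(f"alignment of sequence {rec.id!r} failed: {exc}") from exc

    tasks = [rec for i, rec in enumerate(data) if i != center_index]
    # Pre-computation sample; measured results are discarded and every task
    # is recomputed in the main run for a simpler determinism contract.
    sample = tasks[: max(1, default_sample_size(len(tasks)))]
    plan = plan_partition(len(tasks), pool1, pool2, sample, task, ratio, timer)
    results = pool1.map(task, tasks[: plan.n1])
    if plan.n2:
        results += pool2.map(task, tasks[plan.n1 :])
    if return_partition:
        return results, plan
    return results
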