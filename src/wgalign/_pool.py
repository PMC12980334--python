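"""Deterministic dynamic work pool.

Work units are dispatched to idle workers largest-first (longest-processing-
time order) and the results are reassembled in the original task order, so
the output never depends on the worker count or on completion timing.
"""
from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from typing import Callable, List, Optional, Sequence

from .errors import WorkerError


def run_pool(
    tasks: Sequence,
    worker_fn: Callable,
    workers: int = 1,
    size: Optional[Callable] = None,
) -> List:
    """Apply ``worker_fn`` to every task; results come back in task order.

    ``size`` maps a task to a size hint; bigger tasks are dispatched first
    (dynamic assignment: idle workers pull the next largest pending unit).
    ``worker_fn`` must be pure. A failing task raises WorkerError naming its
    index, chained to the original exception.
    """
    n = len(tasks)
    order = list(range(n))
    if size is not None:
        order.sort(key=lambda i: -size(tasks[i]))  # stable: ties keep task order

    results: List = [None] * n
    if workers <= 1:
        for i in order:
            try:
                results[i] = worker_fn(tasks[i])
            except Exception as exc:
                raise WorkerError(f"task {i} failed: {exc}") from exc
        return results

    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = {i: pool.submit(worker_fn, tasks[i]) for i in order}
        for i in range(n):
            try:
                results[i] = futures[i].result()
            except WorkerError:
                raise
            except Exception as exc:
                raise WorkerError(f"task {i} failed: {exc}") from exc
    return results
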