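"""Classification accuracy/error metrics and the pipeline latency model."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LatencyParams:
    """Pipeline latency parameters.

    stages:
        Number of pipeline stages S (the accelerator uses 8).
    tclk_ns:
        Device clock period in nanoseconds (10 ns at 100 MHz).
    iterations:
        Number of iterations N pushed through the pipeline.
    """

    stages: int = 8
    tclk_ns: float = 10.0
    iterations: int = 30

    def __post_init__(self) -> None:
        if self.stages < 1 or self.iterations < 1:
            raise ValueError("stages and iterations must be at least 1")
        if self.tclk_ns <= 0:
            raise ValueError("tclk_ns must be positive")


def accuracy(n_correct: int, n_total: int) -> float:
    """Percent of correct predictions: 100 * n_correct / n_total.

    Plain arithmetic on the counts; 29 of 30 gives 96.67%, and the function
    makes no attempt to match any differently rounded published figure.
    """
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return 100.0 * n_correct / n_total


def error_rate(acc: float) -> float:
    """Complement of accuracy on the percent scale: 100 - accuracy."""
    if not 0.0 <= acc <= 100.0:
        raise ValueError("accuracy must lie in [0, 100] percent")
    return 100.0 - acc


def pipeline_latency(p: LatencyParams) -> tuple[float, float]:
    """(per-iteration, total) pipeline latency in nanoseconds.

    Per iteration: S x Tclk.  Total for N iterations through a full
    pipeline: (N + S - 1) x Tclk.
    """
    per_iteration = p.stages * p.tclk_ns
    total = (p.iterations + p.stages - 1) * p.tclk_ns
    return per_iteration, total
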