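"""Small reporting helpers shared by the pipeline and the worked examples."""

from __future__ import annotations

from appsig.errors import ValidationError


def percent(count: int, total: int) -> float:
    """100 * count / total, the percentage convention used in all reports."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if count < 0 or count > total:
        raise ValidationError("count must lie in [0, total]")
    return 100.0 * count / total


def pooled_mean(means_and_ns: list[tuple[float, int]]) -> float:
    """Sample-size-weighted mean of per-group means."""
    total = sum(n for _, n in means_and_ns)
    if total <= 0:
        raise ValidationError("group sizes must sum to a positive total")
    return sum(m * n for m, n in means_and_ns) / total
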