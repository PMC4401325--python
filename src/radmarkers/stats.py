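"""Marker bookkeeping statistics and the segregation chi-square screen.

All printed-style statistics round half-up to two decimals, matching the
convention of marker-development reports (e.g. a polymorphism rate of
83/1,323 prints as 6.27%, a marker density of 112,330 kb / 10,619 markers
as "1/10.58 kb").
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy import stats as sps


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def polymorphism_rate(n_poly: int, n_screened: int) -> float:
    """Percent of screened markers that proved polymorphic (2 decimals)."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_poly <= n_screened):
        raise ValueError("need 0 <= n_poly <= n_screened")
    return round_half_up(100.0 * n_poly / n_screened)


def marker_frequency(count: int, total_len_kb: float) -> float:
    """Average kb of assembled sequence per marker (the X of "1/X kb")."""
    if count <= 0:
        raise ValueError("count must be positive")
    return round_half_up(total_len_kb / count)


def mean_map_distance(total_cm: float, n_loci: int) -> float:
    """Mean adjacent-marker distance, total map length / mapped loci (cM)."""
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    return round_half_up(total_cm / n_loci)


_MODELS = {"1:2:1": (1, 2, 1), "3:1": (3, 1)}


@dataclass(frozen=True)
class SegregationResult:
    locus_id: str
    observed: tuple
    model: str
    chi2: float
    pvalue: float
    distorted: bool       # P <= 0.05


def segregation_chisq(observed, model, locus_id: str = "",
                      alpha: float = 0.05) -> SegregationResult:
    """Pearson chi-square of F2 genotype counts against 1:2:1 or 3:1.

    ``model`` may be the string "1:2:1"/"3:1" or any positive ratio tuple
    (the test is invariant under scaling of the ratio).
    """
    if isinstance(model, str):
        label = model
        try:
            ratio = _MODELS[model] if model in _MODELS else tuple(
                float(x) for x in model.split(":")
            )
        except ValueError:
            raise ValueError(f"unparseable model {model!r}") from None
    else:
        ratio = tuple(model)
        label = ":".join(f"{x:g}" for x in ratio)
    observed = tuple(int(x) for x in observed)
    if len(observed) != len(ratio):
        raise ValueError(
            f"model {label} expects {len(ratio)} classes, got {len(observed)}"
        )
    if any(x < 0 for x in observed) or sum(observed) == 0:
        raise ValueError("observed counts must be non-negative with positive sum")
    if any(r <= 0 for r in ratio):
        raise ValueError("model ratio terms must be positive")
    total = sum(observed)
    expected = [total * r / sum(ratio) for r in ratio]
    chi2, p = sps.chisquare(observed, f_exp=expected)
    return SegregationResult(
        locus_id=locus_id, observed=observed, model=label,
        chi2=float(chi2), pvalue=float(p), distorted=bool(p <= alpha),
    )


@dataclass(frozen=True)
class SummaryStats:
    """Scalar summary block of a pipeline run."""

    counts: dict
    polymorphism_rate: float | None = None
    marker_frequency_kb: float | None = None
    tstv: float | None = None
    mean_map_distance_cm: float | None = None


def verify_partition_counts(counts: dict, n_a: int, n_b: int) -> None:
    """Check the partition identity: statuses cover |A| + |B| - |shared pairs|."""
    covered = (counts["shared"] + counts["a_only"] + counts["b_only"]
               + counts["unanchorable"])
    expected = n_a + n_b - counts["shared"]
    if covered != expected:
        raise AssertionError(
            f"partition identity violated: {covered} != {expected} ({counts})"
        )
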