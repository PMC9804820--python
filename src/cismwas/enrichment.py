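"""Annotation enrichment of a selected CpG set against a background.

Builds the 2x2 table of annotation status for a selected set versus the rest
of its background (selected sites must be a subset of the background — e.g.
well-predicted CpGs against all QC-passing CpGs, or trait-associated CpGs
against all CpGs tested in the scan) and reports the sample odds ratio with a
two-sided Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass
class EnrichmentResult:
    annotation: str
    a: int  # selected & annotated
    b: int  # selected & not annotated
    c: int  # background-only & annotated
    d: int  # background-only & not annotated
    odds_ratio: float
    p: float


def enrichment_test(
    selected: set[str],
    background: set[str],
    annotated: set[str],
    name: str = "annotation",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of annotation over-representation.

    The odds ratio is the sample cross-product (a*d)/(b*c); when any cell is
    zero a Haldane +0.5 continuity correction is applied to the odds ratio
    only — the p-value always comes from the uncorrected exact test.
    """
    if not selected:
        raise ValueError("selected set is empty")
    if not selected <= background:
        raise ValueError("selected CpGs must be a subset of the background")
    rest = background - selected
    a = len(selected & annotated)
    b = len(selected) - a
    c = len(rest & annotated)
    d = len(rest) - c
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(annotation=name, a=a, b=b, c=c, d=d, odds_ratio=float(odds), p=float(p))


def enrichment_table(
    selected: set[str],
    background: set[str],
    annotations: dict[str, set[str]],
):
    """Run :func:`enrichment_test` for each named annotation set."""
    return [
        enrichment_test(selected, background, members, name=name)
        for name, members in annotations.items()
    ]
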