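"""Run bookkeeping: per-stage counts and indexing-rate tables.

Serial crystallography lives and dies by its bookkeeping — how many frames
were hits, how many indexed per colour, how many yielded both colours — so
rates are first-class values here, formatted the way processing-stage
summary tables are conventionally printed (count with percentage of the hit
total per stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["percentage", "RunSummary", "indexing_rate_table"]


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """Share of ``count`` in ``total`` as a percentage, rounded.

    E.g. 21,830 of 208,373 hits -> 10.5; 14,782 of 33,297 -> 44.4.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


@dataclass(frozen=True)
class RunSummary:
    """Counts at each stage of a processing run."""

    n_events: int
    n_hits: int
    n_color1: int  # events indexed at the 7 keV colour (strong or weak role)
    n_color2: int  # events indexed at the 9 keV colour
    n_both: int  # events with both colours indexed
    events: tuple[dict, ...] = field(default_factory=tuple)  # per-event records

    def __post_init__(self) -> None:
        if not (0 <= self.n_both <= min(self.n_color1, self.n_color2)
                and max(self.n_color1, self.n_color2) <= self.n_hits <= self.n_events):
            raise ValueError("stage counts must be nested: "
                             "both <= per-colour <= hits <= total")

    def to_frame(self) -> pd.DataFrame:
        """Stage counts with percentages of the event total."""
        rows = [
            ("total events", self.n_events),
            ("hits (> 20 peaks)", self.n_hits),
            ("indexed 7 keV", self.n_color1),
            ("indexed 9 keV", self.n_color2),
            ("indexed 7 and 9 keV", self.n_both),
        ]
        return pd.DataFrame(
            {
                "count": [n for _, n in rows],
                "percent": [percentage(n, self.n_events) for _, n in rows],
            },
            index=[label for label, _ in rows],
        )

    def to_text(self) -> str:
        """Tab-delimited summary table."""
        return self.to_frame().to_csv(sep="\t")


def indexing_rate_table(stage_counts: dict[str, tuple[int, int, int]],
                        total_hits: int) -> pd.DataFrame:
    """Indexing-rate table over processing stages.

    ``stage_counts`` maps a stage label to counts ``(n_7kev, n_9kev,
    n_both)``; each entry is reported with its percentage of ``total_hits``,
    mirroring the conventional per-stage layout.
    """
    rows = {}
    for label, (n7, n9, nb) in stage_counts.items():
        rows[label] = {
            "7 keV": n7, "7 keV %": percentage(n7, total_hits),
            "9 keV": n9, "9 keV %": percentage(n9, total_hits),
            "7 and 9 keV": nb, "7 and 9 keV %": percentage(nb, total_hits),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
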