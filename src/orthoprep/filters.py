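"""Structural orthogroup selection: species missing rate and duplication count.

An orthogroup is retained when

* its species missing rate — the fraction of the roster with zero copies —
  is at most ``max_missing_rate`` (default 0.05), and
* its maximum per-species copy number is at most ``max_duplication_num``
  (default 6), and
* within every multi-copy species all copies are mutually at least
  ``min_similarity`` identical (default 0.97; complete linkage, computed by
  :mod:`orthoprep.simmerge`).

Comparisons are inclusive by default; a ``strict`` flag switches to strict
inequalities.  The missing rate is always evaluated on the original
membership, before any similarity-based rejection, so outcomes are
order-independent.
"""

from __future__ import annotations

import enum
import json
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from .og_model import Orthogroup, OrthogroupSet, SpeciesRoster

__all__ = [
    "Outcome",
    "FilterParams",
    "FilterReport",
    "missing_rate",
    "max_copy_number",
    "passes_structural_filters",
    "filter_orthogroups",
]


class Outcome(str, enum.Enum):
    PASS = "pass"
    FAIL_MISSING = "fail_missing"
    FAIL_DUPLICATION = "fail_duplication"
    FAIL_SIMILARITY = "fail_similarity"


def normalize_similarity(value: float) -> float:
    """Accept a fraction (0.97) or a percentage (97); percentages are divided
    by 100."""
    v = float(value)
    if v > 1.0:
        v = v / 100.0
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"min_similarity out of range: {value!r}")
    return v


@dataclass(frozen=True)
class FilterParams:
    """The three selection thresholds plus policy switches.

    max_missing_rate
        Highest tolerated fraction of absent species (default 0.05).
    max_duplication_num
        Highest tolerated per-species copy count (default 6).
    min_similarity
        Lowest tolerated pairwise identity among same-species copies
        (default 0.97; ``97`` is also accepted and normalised).
    reject_policy
        What to do when a species' copies fail ``min_similarity``:
        ``"drop_orthogroup"`` (default) discards the whole orthogroup,
        ``"drop_species"`` discards only that species' copies.
    strict
        Use strict inequalities instead of the default inclusive ones.
    """

    max_missing_rate: float = 0.05
    max_duplication_num: int = 6
    min_similarity: float = 0.97
    reject_policy: str = "drop_orthogroup"
    strict: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "min_similarity", normalize_similarity(self.min_similarity)
        )
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if self.max_duplication_num < 1:
            raise ValueError("max_duplication_num must be a positive integer")
        if self.reject_policy not in ("drop_orthogroup", "drop_species"):
            raise ValueError(f"unknown reject_policy {self.reject_policy!r}")

    def with_(self, **kw) -> "FilterParams":
        return replace(self, **kw)


@dataclass
class FilterReport:
    """Per-orthogroup outcomes plus the summary distributions."""

    outcomes: dict[str, Outcome]
    missing_rates: dict[str, float]
    max_copies: dict[str, int]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(o.value for o in self.outcomes.values())
        return {o.value: c.get(o.value, 0) for o in Outcome}

    def pass_ids(self) -> list[str]:
        return [og for og, o in self.outcomes.items() if o is Outcome.PASS]

    def missing_rate_histogram(self, n_bins: int = 21) -> dict[str, int]:
        """Counts of orthogroups per missing-rate bin over [0, 1]."""
        hist: Counter = Counter()
        for r in self.missing_rates.values():
            b = min(int(r * (n_bins - 1) + 0.5), n_bins - 1)
            hist[f"{b / (n_bins - 1):.2f}"] += 1
        return dict(sorted(hist.items()))

    def max_copy_histogram(self) -> dict[int, int]:
        """Counts of orthogroups per maximum per-species copy number."""
        return dict(sorted(Counter(self.max_copies.values()).items()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "og_id": list(self.outcomes),
                "outcome": [o.value for o in self.outcomes.values()],
                "missing_rate": [self.missing_rates[k] for k in self.outcomes],
                "max_copy": [self.max_copies[k] for k in self.outcomes],
            }
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def write_json_summary(self, path: str | os.PathLike) -> None:
        summary = {
            "n_orthogroups": len(self.outcomes),
            "counts": self.counts,
            "missing_rate_histogram": self.missing_rate_histogram(),
            "max_copy_histogram": {
                str(k): v for k, v in self.max_copy_histogram().items()
            },
        }
        with open(path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")


def missing_rate(og: Orthogroup, roster: SpeciesRoster) -> float:
    """Fraction of roster species with zero copies in ``og``.

    Genes attributed to species outside the roster do not count toward
    presence, so an orthogroup whose genes all fall outside the roster has
    rate 1.0.
    """
    present = {sp for sp, genes in og.members.items() if genes}
    absent = sum(1 for sp in roster if sp not in present)
    return absent / len(roster)


def max_copy_number(og: Orthogroup) -> int:
    """Maximum per-species copy count; >= 1 for any non-empty orthogroup."""
    return max(len(genes) for genes in og.members.values())


def passes_structural_filters(
    og: Orthogroup, roster: SpeciesRoster, params: FilterParams
) -> Outcome:
    """Missing-rate test first, then duplication; inclusive thresholds by
    default (``strict=True`` switches to ``<``)."""
    rate = missing_rate(og, roster)
    if params.strict:
        if not rate < params.max_missing_rate:
            return Outcome.FAIL_MISSING
        if not max_copy_number(og) < params.max_duplication_num:
            return Outcome.FAIL_DUPLICATION
    else:
        if rate > params.max_missing_rate:
            return Outcome.FAIL_MISSING
        if max_copy_number(og) > params.max_duplication_num:
            return Outcome.FAIL_DUPLICATION
    return Outcome.PASS


def filter_orthogroups(
    ogset: OrthogroupSet,
    params: FilterParams,
    align_params=None,
    check_similarity: bool = True,
) -> tuple[OrthogroupSet, FilterReport]:
    """Apply all selection criteria, preserving input order.

    Returns the retained orthogroups (original membership; under
    ``reject_policy="drop_species"`` the failing species are pruned later,
    during merging) and a :class:`FilterReport` whose outcomes partition the
    input.  With ``check_similarity=False`` only the structural criteria are
    applied.
    """
    from . import simmerge  # deferred: simmerge imports FilterParams from here

    if align_params is None:
        align_params = simmerge.AlignmentParams()

    outcomes: dict[str, Outcome] = {}
    rates: dict[str, float] = {}
    copies: dict[str, int] = {}
    kept: list[Orthogroup] = []
    for og in ogset:
        rates[og.og_id] = missing_rate(og, ogset.roster)
        copies[og.og_id] = max_copy_number(og)
        outcome = passes_structural_filters(og, ogset.roster, params)
        if outcome is Outcome.PASS and check_similarity:
            for sp in ogset.roster:
                genes = og.members.get(sp, [])
                if len(genes) < 2:
                    continue
                ok, _ = simmerge.copies_mergeable(
                    genes, params.min_similarity, align_params
                )
                if not ok and params.reject_policy == "drop_orthogroup":
                    outcome = Outcome.FAIL_SIMILARITY
                    break
                # drop_species: orthogroup stays; pruning happens at merge time
        outcomes[og.og_id] = outcome
        if outcome is Outcome.PASS:
            kept.append(og)
    report = FilterReport(outcomes, rates, copies)
    return OrthogroupSet(ogset.roster, kept), report
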