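"""Cohort comparison designs and transmission-pattern reduction.

Three study layouts are supported:

* ``mother_infant`` — one maternal faecal sample per family, compared
  against the infant's samples at days 4, 7, 21 and during infancy
  (6-15 months).  Comparisons never cross families.
* ``pregnancy`` — longitudinal samples from one woman pooled into
  gestational-day bins (1-100, 101-150, 151-200, 201-300); the early
  bin is compared against each later bin present.
* ``fmt_mouse`` — a human donor faecal sample, the gnotobiotic dam it
  was transplanted into, and the dam's F1 litter; donor-dam, donor-F1
  and dam-F1 comparisons.

Per-species relatedness calls for each comparison are reduced to the
categorical transmission patterns used to summarise such cohorts
(shared at all time points, mixed, never shared; donor/dam engraftment
patterns), and per-family summaries (only related / mosaic / only
unrelated).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .core import DepthTrack, Pileup

MOTHER_INFANT_TIMEPOINTS = ("infant_day4", "infant_day7", "infant_day21", "infancy")
GESTATIONAL_BINS = (
    ("1-100", 1, 100),
    ("101-150", 101, 150),
    ("151-200", 151, 200),
    ("201-300", 201, 300),
)

ROLES = frozenset(
    {
        "mother",
        "infant_day4",
        "infant_day7",
        "infant_day21",
        "infancy",
        "gestational_bin",
        "donor",
        "dam",
        "f1",
    }
)


class Call(str, Enum):
    RELATED = "related"
    UNRELATED = "unrelated"
    NO_CALL = "no_call"


class TimepointPattern(str, Enum):
    """Per-species pattern across a mother-infant pair's time points."""

    SHARED_ALL = "shared_all_timepoints"
    MIXED = "mixed_timepoints"
    NEVER_SHARED = "never_shared"
    INSUFFICIENT = "insufficient_data"


class FmtPattern(str, Enum):
    """Per-species engraftment pattern in a donor/dam/F1 trio."""

    DONOR_AND_DAM = "donor_and_dam_related"
    DAM_ONLY = "dam_only_related"
    DONOR_ONLY = "donor_only_related"
    ALL_UNRELATED = "all_unrelated"
    INSUFFICIENT = "insufficient_data"


class SubjectSummary(str, Enum):
    """Family-level summary across all species and time points."""

    ONLY_RELATED = "only_related"
    MOSAIC = "mosaic"
    ONLY_UNRELATED = "only_unrelated"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class SubjectSample:
    sample_id: str
    family_id: str
    role: str
    day: int | None = None  # gestational day, pregnancy designs only

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class CohortDesign:
    """A comparison design: who is compared with whom.

    ``lineages`` optionally records, for simulated cohorts, which strain
    lineage each (sample, species) carries; two samples of a family are
    truly related for a species iff their lineage labels match.  Real
    cohorts leave it None.
    """

    cohort_type: str  # mother_infant | pregnancy | fmt_mouse
    samples: list[SubjectSample]
    species: list[str] = field(default_factory=list)
    lineages: dict[tuple[str, str], str] | None = None

    def __post_init__(self) -> None:
        if self.cohort_type not in {"mother_infant", "pregnancy", "fmt_mouse"}:
            raise ValueError(f"unknown cohort type {self.cohort_type!r}")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in design")

    def families(self) -> dict[str, list[SubjectSample]]:
        fams: dict[str, list[SubjectSample]] = defaultdict(list)
        for s in self.samples:
            fams[s.family_id].append(s)
        return dict(fams)


def gestational_bin(day: int) -> str:
    """Map a gestational day to its pooling bin (boundaries inclusive)."""
    for label, lo, hi in GESTATIONAL_BINS:
        if lo <= day <= hi:
            return label
    raise ValueError(f"gestational day {day} outside 1-300")


def build_pairings(design: CohortDesign) -> list[tuple[str, str]]:
    """Enumerate the sample comparisons the design mandates.

    Pairings stay within families; the anchor sample (mother, early
    gestational bin, or donor) must be present in each family.
    """
    pairs: list[tuple[str, str]] = []
    for family_id, members in sorted(design.families().items()):
        by_role: dict[str, list[SubjectSample]] = defaultdict(list)
        for m in members:
            by_role[m.role].append(m)
        if design.cohort_type == "mother_infant":
            if not by_role.get("mother"):
                raise ValueError(f"family {family_id}: no mother sample")
            mother = by_role["mother"][0]
            for role in MOTHER_INFANT_TIMEPOINTS:
                for inf in by_role.get(role, []):
                    pairs.append((mother.sample_id, inf.sample_id))
        elif design.cohort_type == "pregnancy":
            bins: dict[str, SubjectSample] = {}
            for m in members:
                if m.day is None:
                    raise ValueError(f"sample {m.sample_id}: gestational day missing")
                bins[gestational_bin(m.day)] = m
            if "1-100" not in bins:
                raise ValueError(f"subject {family_id}: no early (1-100 day) bin")
            early = bins["1-100"]
            for label, _, _ in GESTATIONAL_BINS[1:]:
                if label in bins:
                    pairs.append((early.sample_id, bins[label].sample_id))
        else:  # fmt_mouse
            if not by_role.get("donor"):
                raise ValueError(f"litter {family_id}: no donor sample")
            donor = by_role["donor"][0]
            dam = by_role["dam"][0] if by_role.get("dam") else None
            if dam is not None:
                pairs.append((donor.sample_id, dam.sample_id))
            for f1 in by_role.get("f1", []):
                pairs.append((donor.sample_id, f1.sample_id))
                if dam is not None:
                    pairs.append((dam.sample_id, f1.sample_id))
    return pairs


def merge_gestational_bins(
    samples_with_days: list[tuple[int, Pileup, DepthTrack]],
) -> dict[str, tuple[Pileup, DepthTrack]]:
    """Pool per-day pileups of one subject into gestational bins.

    Pooling sums allele counts and depth elementwise, equivalent to
    concatenating the reads of all collection days in the bin before
    profiling.
    """
    out: dict[str, tuple[Pileup, DepthTrack]] = {}
    for day, pileup, depth in samples_with_days:
        label = gestational_bin(day)
        if label in out:
            prev_p, prev_d = out[label]
            out[label] = (
                prev_p.pooled_with(pileup),
                DepthTrack(depth.species_id, prev_d.depth + depth.depth),
            )
        else:
            out[label] = (
                Pileup(pileup.species_id, pileup.counts.copy()),
                DepthTrack(depth.species_id, depth.depth.copy()),
            )
    return out


def _as_calls(values) -> list[Call]:
    return [Call(v) for v in values]


def mother_infant_pattern(calls_by_timepoint: dict[str, str | Call]) -> TimepointPattern:
    """Reduce one species' call vector over time points to a pattern.

    no_call entries are ignored rather than counted as unrelated: a
    species without coverage or cut-off at some time point carries no
    evidence either way.
    """
    calls = [c for c in _as_calls(calls_by_timepoint.values()) if c is not Call.NO_CALL]
    if not calls:
        return TimepointPattern.INSUFFICIENT
    if all(c is Call.RELATED for c in calls):
        return TimepointPattern.SHARED_ALL
    if all(c is Call.UNRELATED for c in calls):
        return TimepointPattern.NEVER_SHARED
    return TimepointPattern.MIXED


def fmt_pattern(
    donor_f1_call: str | Call,
    dam_f1_call: str | Call,
    donor_dam_call: str | Call = Call.NO_CALL,
) -> FmtPattern:
    """Classify a donor/dam/F1 call triple into an engraftment pattern."""
    donor_f1 = Call(donor_f1_call)
    dam_f1 = Call(dam_f1_call)
    donor_dam = Call(donor_dam_call)
    if donor_f1 is Call.RELATED and dam_f1 is Call.RELATED:
        return FmtPattern.DONOR_AND_DAM
    if dam_f1 is Call.RELATED:
        return FmtPattern.DAM_ONLY
    if donor_f1 is Call.RELATED:
        return FmtPattern.DONOR_ONLY
    available = [c for c in (donor_f1, dam_f1, donor_dam) if c is not Call.NO_CALL]
    if available and all(c is Call.UNRELATED for c in available):
        return FmtPattern.ALL_UNRELATED
    return FmtPattern.INSUFFICIENT


def subject_summary(calls_across_species: dict[str, dict[str, str | Call]]) -> SubjectSummary:
    """Summarise one family over every species and comparison.

    ``only_related`` requires every informative call to be related;
    ``mosaic`` needs at least one related and one unrelated call.
    """
    flat: list[Call] = []
    for per_tp in calls_across_species.values():
        flat.extend(c for c in _as_calls(per_tp.values()) if c is not Call.NO_CALL)
    if not flat:
        return SubjectSummary.INSUFFICIENT
    has_rel = any(c is Call.RELATED for c in flat)
    has_unrel = any(c is Call.UNRELATED for c in flat)
    if has_rel and has_unrel:
        return SubjectSummary.MOSAIC
    return SubjectSummary.ONLY_RELATED if has_rel else SubjectSummary.ONLY_UNRELATED


def pattern_table(
    calls: pd.DataFrame, cohort_type: str = "mother_infant"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-(family, species) patterns and family summaries.

    ``calls`` needs columns family, species, comparison, call, where
    ``comparison`` labels the time point (mother_infant) or the trio leg
    donor_f1 / dam_f1 / donor_dam (fmt_mouse).  Returns the pattern
    table and a family-summary table, both deterministically sorted.
    """
    required = {"family", "species", "comparison", "call"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"calls table missing columns {sorted(missing)}")
    pattern_rows = []
    summary_rows = []
    for family, fam_df in calls.groupby("family", sort=True):
        per_species: dict[str, dict[str, str]] = {}
        for species, sp_df in fam_df.groupby("species", sort=True):
            vec = dict(zip(sp_df["comparison"], sp_df["call"]))
            per_species[str(species)] = vec
            if cohort_type == "fmt_mouse":
                pat = fmt_pattern(
                    vec.get("donor_f1", Call.NO_CALL),
                    vec.get("dam_f1", Call.NO_CALL),
                    vec.get("donor_dam", Call.NO_CALL),
                ).value
            else:
                pat = mother_infant_pattern(vec).value
            pattern_rows.append(
                {"family": family, "species": species, "pattern": pat}
            )
        summary_rows.append(
            {"family": family, "summary": subject_summary(per_species).value}
        )
    patterns = pd.DataFrame(pattern_rows, columns=["family", "species", "pattern"])
    if not patterns.empty:
        patterns = patterns.sort_values(["family", "species"], ignore_index=True)
    summary = pd.DataFrame(summary_rows, columns=["family", "summary"])
    if not summary.empty:
        summary = summary.sort_values("family", ignore_index=True)
    return patterns, summary
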