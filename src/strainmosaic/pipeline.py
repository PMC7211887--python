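"""End-to-end composition of the strain-tracking stages.

These helpers wire the module-level operations together for whole
cohorts: consensus-profile every sample, score every designed
comparison, classify against per-species cut-offs, and reduce to
transmission patterns.  They operate equally on simulated cohorts
(with ground truth attached) and on profiles/depth tracks ingested
from real files.
"""

from __future__ import annotations

import pandas as pd

from .calibration import SpeciesCutoff, calibrate_cutoff
from .cohort import MOTHER_INFANT_TIMEPOINTS, build_pairings, pattern_table
from .core import DepthTrack, Pileup, ReferenceSequence, SNVProfile
from .ingest import call_consensus_snvs
from .synthetic_data import CohortDataset, simulate_calibration_pairs
from .wss import WSSParams, classify_pair, make_windows, wss_score


def profile_sample(
    pileup: Pileup,
    reference: ReferenceSequence,
    sample_id: str,
    min_depth: int = 5,
    min_allele_fraction: float = 0.8,
) -> SNVProfile:
    return call_consensus_snvs(pileup, reference, sample_id, min_depth, min_allele_fraction)


def score_cohort(
    dataset: CohortDataset,
    cutoffs: dict[str, SpeciesCutoff] | dict[str, float] | None = None,
    params: WSSParams = WSSParams(),
) -> pd.DataFrame:
    """Score every designed comparison of a simulated cohort.

    Returns one row per (species, sample pair) with the WSS score, QC
    outcome and — when a cut-off is available — the related/unrelated
    call and the planted truth label.
    """
    design = dataset.design
    profiles: dict[tuple[str, str], SNVProfile] = {}
    depths: dict[tuple[str, str], DepthTrack] = {}
    windows = {
        sp: make_windows(ref.length, params.window_size, sp)
        for sp, ref in dataset.references.items()
    }
    for (sample_id, sp), pu in dataset.pileups.items():
        profiles[(sample_id, sp)] = profile_sample(pu, dataset.references[sp], sample_id)
        depths[(sample_id, sp)] = pu.depth_track()
    rows = []
    for a, b in build_pairings(design):
        for sp in design.species:
            if (a, sp) not in profiles or (b, sp) not in profiles:
                continue
            res = wss_score(
                profiles[(a, sp)],
                profiles[(b, sp)],
                depths[(a, sp)],
                depths[(b, sp)],
                windows[sp],
                params,
            )
            cutoff = None
            if cutoffs is not None and sp in cutoffs:
                c = cutoffs[sp]
                cutoff = c.cutoff if isinstance(c, SpeciesCutoff) else float(c)
            res = classify_pair(res, cutoff)
            rows.append(
                {
                    "species": sp,
                    "sample_a": a,
                    "sample_b": b,
                    "score": res.score,
                    "n_windows_retained": res.n_windows_retained,
                    "qc_pass": res.qc.passed,
                    "call": res.call,
                    "truth": dataset.truth_labels.get(((a, b), sp)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "sample_a",
            "sample_b",
            "score",
            "n_windows_retained",
            "qc_pass",
            "call",
            "truth",
        ],
    )


def calibrate_species(
    reference: ReferenceSequence,
    n_related: int = 20,
    n_unrelated: int = 20,
    mean_depth: float = 20.0,
    base_error_rate: float = 0.001,
    strain_divergence: float = 0.005,
    seed: int = 0,
    params: WSSParams = WSSParams(),
) -> SpeciesCutoff:
    """Calibrate one species' cut-off from simulated labelled pairs."""
    pairs = simulate_calibration_pairs(
        reference,
        n_related,
        n_unrelated,
        mean_depth,
        base_error_rate,
        strain_divergence,
        seed,
    )
    related, unrelated = [], []
    windows = make_windows(reference.length, params.window_size, reference.species_id)
    for i, pair in enumerate(pairs):
        prof_a = profile_sample(pair.pileup_a, reference, f"train{i}a")
        prof_b = profile_sample(pair.pileup_b, reference, f"train{i}b")
        res = wss_score(prof_a, prof_b, pair.depth_a, pair.depth_b, windows, params)
        if res.score is None:
            continue
        (related if pair.label == "related" else unrelated).append(res.score)
    return calibrate_cutoff(related, unrelated, reference.species_id)


def cohort_summary(
    dataset: CohortDataset,
    cutoffs: dict[str, SpeciesCutoff] | dict[str, float],
    params: WSSParams = WSSParams(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full pipeline: scores, per-species patterns, family summaries."""
    scores = score_cohort(dataset, cutoffs, params)
    design = dataset.design
    role_of = {s.sample_id: s.role for s in design.samples}
    family_of = {s.sample_id: s.family_id for s in design.samples}

    if design.cohort_type == "fmt_mouse":
        patterns = fmt_trio_patterns(scores, dataset.design)
        calls = pd.DataFrame(
            {
                "family": [family_of[a] for a in scores["sample_a"]],
                "species": scores["species"],
                "comparison": scores["sample_a"] + "|" + scores["sample_b"],
                "call": scores["call"],
            }
        )
        _, summary = pattern_table(calls, cohort_type="mother_infant")
        return scores, patterns, summary

    calls = pd.DataFrame(
        {
            "family": [family_of[a] for a in scores["sample_a"]],
            "species": scores["species"],
            "comparison": (
                [role_of[b] for b in scores["sample_b"]]
                if design.cohort_type == "mother_infant"
                else list(scores["sample_b"])
            ),
            "call": scores["call"],
        }
    )
    patterns, summary = pattern_table(calls, cohort_type=design.cohort_type)
    return scores, patterns, summary


def fmt_trio_patterns(scores: pd.DataFrame, design) -> pd.DataFrame:
    """Per-(family, F1, species) engraftment patterns for FMT cohorts.

    Each F1 animal is classified from its donor-F1 and dam-F1 calls
    together with the family's donor-dam call.
    """
    from .cohort import fmt_pattern

    role_of = {s.sample_id: s.role for s in design.samples}
    family_of = {s.sample_id: s.family_id for s in design.samples}
    rows = []
    for (family, species), df in scores.groupby(
        [scores["sample_a"].map(family_of), "species"], sort=True
    ):
        donor_dam = "no_call"
        donor_f1: dict[str, str] = {}
        dam_f1: dict[str, str] = {}
        for r in df.itertuples():
            ra, rb = role_of[r.sample_a], role_of[r.sample_b]
            if (ra, rb) == ("donor", "dam"):
                donor_dam = r.call
            elif (ra, rb) == ("donor", "f1"):
                donor_f1[r.sample_b] = r.call
            elif (ra, rb) == ("dam", "f1"):
                dam_f1[r.sample_b] = r.call
        for f1 in sorted(set(donor_f1) | set(dam_f1)):
            pat = fmt_pattern(
                donor_f1.get(f1, "no_call"), dam_f1.get(f1, "no_call"), donor_dam
            )
            rows.append(
                {"family": family, "f1": f1, "species": species, "pattern": pat.value}
            )
    return pd.DataFrame(rows, columns=["family", "f1", "species", "pattern"])
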