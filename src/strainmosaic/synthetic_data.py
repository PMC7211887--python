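"""Synthetic strain, sequencing and cohort simulation.

Everything downstream of raw sequencing is testable against this
module: it generates reference genomes, strain genomes at controlled
SNV divergence, Poisson-depth pileups with base-call errors and
contiguous coverage dropout, SAM alignment records (to exercise the
multi-mapper / identity filters), labelled related/unrelated
calibration pairs mimicking a same-individual-resequenced design, full
cohort layouts with ground-truth lineage labels, and grouped taxa
abundance tables for community statistics.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so a cohort is reproducible
from one number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    MOTHER_INFANT_TIMEPOINTS,
    CohortDesign,
    SubjectSample,
    build_pairings,
)
from .core import BASE_INDEX, BASES, DepthTrack, Pileup, ReferenceSequence
from .core import AlignmentRecord

__all__ = [
    "StrainGenome",
    "SimulatedSample",
    "CohortDataset",
    "make_reference",
    "mutate_strain",
    "drift_strain",
    "simulate_pileup",
    "simulate_alignments",
    "simulate_cohort",
    "simulate_calibration_pairs",
    "simulate_abundance_table",
    "mother_infant_cohort_design",
    "fmt_cohort_design",
    "write_fasta",
    "write_sam",
    "write_truth_tsv",
]

@dataclass(frozen=True)
class StrainGenome:
    """A strain: a reference plus a sparse map of SNVs.

    ``snvs`` maps 1-based positions to the alternate base carried by
    the strain; ``divergence`` is the per-base substitution probability
    the strain was generated with.
    """

    reference: ReferenceSequence
    snvs: dict[int, str]
    divergence: float
    lineage_id: str

    def __post_init__(self) -> None:
        L = self.reference.length
        for pos, alt in self.snvs.items():
            if not 1 <= pos <= L:
                raise ValueError(f"SNV position {pos} outside reference")
            if alt == self.reference.sequence[pos - 1]:
                raise ValueError(f"SNV at {pos} equals the reference base")

    def sequence(self) -> str:
        seq = list(self.reference.sequence)
        for pos, alt in self.snvs.items():
            seq[pos - 1] = alt
        return "".join(seq)

    def allele_indices(self) -> np.ndarray:
        """Per-position ACGT index of the strain's own allele."""
        idx = self.reference.base_indices().copy()
        for pos, alt in self.snvs.items():
            idx[pos - 1] = BASE_INDEX[alt]
        return idx


@dataclass
class SimulatedSample:
    sample_id: str
    role: str
    strains: list[tuple[StrainGenome, float]]  # (strain, relative depth)
    seed: int

    def __post_init__(self) -> None:
        for _, rel_depth in self.strains:
            if rel_depth <= 0:
                raise ValueError("relative depth must be positive")


@dataclass
class CohortDataset:
    """A simulated cohort with ground truth.

    ``truth_labels`` maps (ordered sample pair, species) to
    related/unrelated, covering every comparison the design mandates.
    """

    design: CohortDesign
    references: dict[str, ReferenceSequence]
    samples: list[SimulatedSample]
    pileups: dict[tuple[str, str], Pileup]  # (sample_id, species_id)
    truth_labels: dict[tuple[tuple[str, str], str], str]


def make_reference(
    species_id: str,
    length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    name: str | None = None,
) -> ReferenceSequence:
    """Draw a random reference genome with the requested GC content."""
    if length < 1000:
        raise ValueError("reference length must be at least 1000 bp")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    idx = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[i] for i in idx)
    return ReferenceSequence(species_id, name or species_id, seq)


def mutate_strain(
    reference: ReferenceSequence,
    divergence: float,
    seed: int = 0,
    lineage_id: str = "lineage",
) -> StrainGenome:
    """Derive a strain by placing Binomial(L, divergence) SNVs uniformly."""
    if not 0 <= divergence <= 0.05:
        raise ValueError("divergence must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    L = reference.length
    n_snv = int(rng.binomial(L, divergence))
    positions = rng.choice(L, size=n_snv, replace=False) + 1
    snvs: dict[int, str] = {}
    for pos in sorted(int(p) for p in positions):
        ref_base = reference.sequence[pos - 1]
        choices = [b for b in BASES if b != ref_base]
        if ref_base == "N":
            choices = list(BASES)
        snvs[pos] = choices[rng.integers(len(choices))]
    return StrainGenome(reference, snvs, divergence, lineage_id)


def drift_strain(
    strain: StrainGenome, divergence: float, seed: int = 0, lineage_id: str | None = None
) -> StrainGenome:
    """Apply within-host drift: further substitutions on top of a strain.

    A drift hit at an existing SNV site redraws the allele (possibly
    reverting it to the reference, in which case the SNV disappears).
    """
    if not 0 <= divergence <= 0.05:
        raise ValueError("divergence must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    L = strain.reference.length
    n = int(rng.binomial(L, divergence))
    positions = rng.choice(L, size=n, replace=False) + 1
    snvs = dict(strain.snvs)
    for pos in sorted(int(p) for p in positions):
        current = snvs.get(pos, strain.reference.sequence[pos - 1])
        choices = [b for b in BASES if b != current]
        new = choices[rng.integers(len(choices))]
        if new == strain.reference.sequence[pos - 1]:
            snvs.pop(pos, None)
        else:
            snvs[pos] = new
    return StrainGenome(
        strain.reference, snvs, strain.divergence, lineage_id or strain.lineage_id
    )


def simulate_pileup(
    strain: StrainGenome,
    mean_depth: float,
    depth_dropout_fraction: float = 0.0,
    base_error_rate: float = 0.0,
    seed: int = 0,
    dropout_block: int = 500,
) -> tuple[Pileup, DepthTrack]:
    """Simulate per-position allele counts for one sequenced sample.

    Depth is Poisson(mean_depth) per position; a ``depth_dropout_fraction``
    of the genome is zeroed in contiguous blocks of ``dropout_block`` bp
    (coverage gaps in real data are contiguous, and breadth-of-coverage
    QC should see realistic gaps, not salt-and-pepper missingness).
    Each base call reports the strain allele with probability
    ``1 - base_error_rate`` and a uniformly chosen other base otherwise.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= depth_dropout_fraction < 1:
        raise ValueError("dropout fraction must lie in [0, 1)")
    if not 0 <= base_error_rate <= 0.05:
        raise ValueError("base_error_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    L = strain.reference.length
    depth = rng.poisson(mean_depth, size=L)
    if depth_dropout_fraction > 0:
        n_blocks = int(np.ceil(L / dropout_block))
        n_drop = int(round(depth_dropout_fraction * n_blocks))
        dropped = rng.choice(n_blocks, size=n_drop, replace=False)
        for b in dropped:
            depth[b * dropout_block : (b + 1) * dropout_block] = 0
    counts = np.zeros((L, 4), dtype=np.int64)
    allele = strain.allele_indices()
    e = base_error_rate
    for b in range(4):
        mask = allele == b
        if not mask.any():
            continue
        p = np.full(4, e / 3)
        p[b] = 1 - e
        counts[mask] = rng.multinomial(depth[mask], p)
    # N reference positions (allele -1): spread uniformly
    mask = allele < 0
    if mask.any():
        counts[mask] = rng.multinomial(depth[mask], np.full(4, 0.25))
    return Pileup(strain.reference.species_id, counts), DepthTrack(
        strain.reference.species_id, depth
    )


def simulate_alignments(
    strain: StrainGenome,
    read_length: int,
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
    secondary_fraction: float = 0.0,
) -> list[AlignmentRecord]:
    """Simulate ungapped aligned reads from a strain genome.

    Edit distances are computed against the *reference* (as an aligner
    would report them), so they include both the strain's SNVs and the
    simulated base errors.  A ``secondary_fraction`` of records is
    flagged secondary to exercise the multi-mapper filter; the flag is
    set directly rather than simulating genuine repeats, since the
    filter inspects flags only.
    """
    if read_length < 50:
        raise ValueError("read_length must be at least 50")
    if read_length > strain.reference.length:
        raise ValueError("read_length exceeds reference length")
    if n_reads < 1:
        raise ValueError("n_reads must be at least 1")
    rng = np.random.default_rng(seed)
    L = strain.reference.length
    genome = strain.sequence()
    ref = strain.reference.sequence
    records: list[AlignmentRecord] = []
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    n_secondary = int(round(secondary_fraction * n_reads))
    secondary_ids = set(rng.choice(n_reads, size=n_secondary, replace=False).tolist())
    for i, start in enumerate(starts):
        start = int(start)
        read = list(genome[start : start + read_length])
        if error_rate > 0:
            hits = np.nonzero(rng.random(read_length) < error_rate)[0]
            for h in hits:
                choices = [b for b in BASES if b != read[h]]
                read[h] = choices[rng.integers(3)]
        seq = "".join(read)
        nm = sum(a != b for a, b in zip(seq, ref[start : start + read_length]))
        records.append(
            AlignmentRecord(
                read_id=f"read{i:06d}",
                species_id=strain.reference.species_id,
                pos=start + 1,
                aligned_length=read_length,
                edit_distance=nm,
                is_secondary=i in secondary_ids,
                sequence=seq,
            )
        )
    return records


# ---------------------------------------------------------------------------
# cohort designs with planted lineage truth
# ---------------------------------------------------------------------------


def mother_infant_cohort_design(
    n_only_related: int = 3,
    n_mosaic: int = 12,
    species: tuple[str, ...] = ("sp01", "sp02", "sp03"),
    timepoints: tuple[str, ...] = MOTHER_INFANT_TIMEPOINTS,
    seed: int = 0,
) -> CohortDesign:
    """A vaginal-birth style cohort with planted family-level outcomes.

    ``n_only_related`` families share the maternal lineage for every
    species at every time point; ``n_mosaic`` families carry at least
    one maternal and at least one foreign lineage, with the foreign
    slots drawn at random.
    """
    rng = np.random.default_rng(seed)
    samples: list[SubjectSample] = []
    lineages: dict[tuple[str, str], str] = {}
    n_fam = n_only_related + n_mosaic
    for f in range(n_fam):
        fam = f"fam{f:02d}"
        mosaic = f >= n_only_related
        mother_id = f"{fam}_mother"
        samples.append(SubjectSample(mother_id, fam, "mother"))
        for sp in species:
            lineages[(mother_id, sp)] = f"{fam}:{sp}:maternal"
        slots = [(sp, tp) for sp in species for tp in timepoints]
        foreign: set[tuple[str, str]] = set()
        if mosaic:
            # at least one foreign and at least one maternal slot
            k = int(rng.integers(1, len(slots)))
            chosen = rng.choice(len(slots), size=k, replace=False)
            foreign = {slots[int(c)] for c in chosen}
        for tp in timepoints:
            sid = f"{fam}_{tp}"
            samples.append(SubjectSample(sid, fam, tp))
            for sp in species:
                if (sp, tp) in foreign:
                    lineages[(sid, sp)] = f"{fam}:{sp}:environmental:{tp}"
                else:
                    lineages[(sid, sp)] = f"{fam}:{sp}:maternal"
    return CohortDesign("mother_infant", samples, list(species), lineages)


def fmt_cohort_design(
    pattern_by_species: dict[str, str],
    n_f1: int = 4,
    family_id: str = "donor1",
) -> CohortDesign:
    """One donor/dam/F1 litter with a planted per-species pattern.

    Patterns: ``donor_and_dam_related`` (donor lineage throughout),
    ``dam_only_related`` (dam and F1s share a lineage absent from the
    donor), ``donor_only_related`` (F1s carry the donor lineage but the
    dam does not), ``all_unrelated`` (every animal its own lineage).
    """
    allowed = {
        "donor_and_dam_related",
        "dam_only_related",
        "donor_only_related",
        "all_unrelated",
    }
    species = sorted(pattern_by_species)
    samples = [
        SubjectSample(f"{family_id}_donor", family_id, "donor"),
        SubjectSample(f"{family_id}_dam", family_id, "dam"),
    ]
    samples += [
        SubjectSample(f"{family_id}_f1_{i}", family_id, "f1") for i in range(1, n_f1 + 1)
    ]
    lineages: dict[tuple[str, str], str] = {}
    for sp in species:
        pat = pattern_by_species[sp]
        if pat not in allowed:
            raise ValueError(f"unknown planted pattern {pat!r}")
        donor_lin = f"{family_id}:{sp}:donor"
        lineages[(f"{family_id}_donor", sp)] = donor_lin
        if pat == "donor_and_dam_related":
            dam_lin = f1_lin = donor_lin
        elif pat == "dam_only_related":
            dam_lin = f1_lin = f"{family_id}:{sp}:dam"
        elif pat == "donor_only_related":
            dam_lin, f1_lin = f"{family_id}:{sp}:dam", donor_lin
        else:  # all_unrelated
            dam_lin, f1_lin = f"{family_id}:{sp}:dam", None
        lineages[(f"{family_id}_dam", sp)] = dam_lin
        for i in range(1, n_f1 + 1):
            lineages[(f"{family_id}_f1_{i}", sp)] = (
                f1_lin if f1_lin else f"{family_id}:{sp}:f1_{i}"
            )
    return CohortDesign("fmt_mouse", samples, species, lineages)


def simulate_cohort(
    design: CohortDesign,
    related_divergence: float = 0.0,
    unrelated_divergence: float = 0.005,
    seed: int = 0,
    reference_length: int = 20_000,
    gc_fraction: float = 0.5,
    mean_depth: float = 20.0,
    base_error_rate: float = 0.001,
    depth_dropout_fraction: float = 0.0,
) -> CohortDataset:
    """Sequence a designed cohort into per-sample pileups with truth.

    Samples of a family sharing a lineage label carry the identical
    strain genome, independently re-sequenced (optionally drifted by
    ``related_divergence``, default 0: the related/unrelated dichotomy
    assumes strain persistence).  Distinct lineages get independent
    strains at ``unrelated_divergence`` from the reference, hence about
    twice that from each other.
    """
    if design.lineages is None:
        raise ValueError("design carries no lineage truth; cannot simulate")
    if related_divergence >= unrelated_divergence and unrelated_divergence > 0:
        raise ValueError("related drift must stay below unrelated divergence")
    ss = np.random.SeedSequence(seed)
    ref_seeds, strain_seeds, sample_seeds = ss.spawn(3)

    references: dict[str, ReferenceSequence] = {}
    for sp, child in zip(design.species, ref_seeds.spawn(len(design.species))):
        references[sp] = make_reference(
            sp, reference_length, gc_fraction, seed=int(child.generate_state(1)[0] % 2**31)
        )

    # one strain genome per (family-scoped) lineage label
    lineage_names = sorted(set(design.lineages.values()))
    strains: dict[str, StrainGenome] = {}
    for lin, child in zip(lineage_names, strain_seeds.spawn(len(lineage_names))):
        sp = lin.split(":")[1] if ":" in lin else design.species[0]
        strains[lin] = mutate_strain(
            references[sp],
            unrelated_divergence,
            seed=int(child.generate_state(1)[0] % 2**31),
            lineage_id=lin,
        )

    samples: list[SimulatedSample] = []
    pileups: dict[tuple[str, str], Pileup] = {}
    depth_tracks: dict[tuple[str, str], DepthTrack] = {}
    sample_children = sample_seeds.spawn(len(design.samples))
    for subj, child in zip(design.samples, sample_children):
        sub = child.spawn(len(design.species))
        sample_strains: list[tuple[StrainGenome, float]] = []
        for sp, sp_child in zip(design.species, sub):
            lin = design.lineages.get((subj.sample_id, sp))
            if lin is None:
                continue
            strain = strains[lin]
            s1, s2 = (int(x.generate_state(1)[0] % 2**31) for x in sp_child.spawn(2))
            if related_divergence > 0:
                strain = drift_strain(strain, related_divergence, seed=s1)
            sample_strains.append((strain, 1.0))
            pu, dt = simulate_pileup(
                strain,
                mean_depth,
                depth_dropout_fraction=depth_dropout_fraction,
                base_error_rate=base_error_rate,
                seed=s2,
            )
            pileups[(subj.sample_id, sp)] = pu
            depth_tracks[(subj.sample_id, sp)] = dt
        samples.append(
            SimulatedSample(
                subj.sample_id,
                subj.role,
                sample_strains,
                seed=int(child.generate_state(1)[0] % 2**31),
            )
        )

    truth: dict[tuple[tuple[str, str], str], str] = {}
    for a, b in build_pairings(design):
        for sp in design.species:
            la = design.lineages.get((a, sp))
            lb = design.lineages.get((b, sp))
            if la is None or lb is None:
                continue
            truth[((a, b), sp)] = "related" if la == lb else "unrelated"
    return CohortDataset(design, references, samples, pileups, truth)


@dataclass
class LabelledPair:
    """One calibration pair: two sequenced samples with a truth label."""

    label: str  # related | unrelated
    pileup_a: Pileup
    pileup_b: Pileup
    depth_a: DepthTrack
    depth_b: DepthTrack


def simulate_calibration_pairs(
    reference: ReferenceSequence,
    n_related: int = 20,
    n_unrelated: int = 20,
    mean_depth: float = 20.0,
    base_error_rate: float = 0.001,
    strain_divergence: float = 0.005,
    seed: int = 0,
) -> list[LabelledPair]:
    """Labelled pairs mimicking a same-individual-resequenced design.

    A related pair is one strain sequenced twice with independent noise
    (the two samples of one individual at separate times); an unrelated
    pair is two independent strains, each at ``strain_divergence`` from
    the reference (two different individuals).
    """
    pairs: list[LabelledPair] = []
    children = np.random.SeedSequence(seed).spawn(n_related + n_unrelated)
    for i, child in enumerate(children):
        related = i < n_related
        s = [int(x.generate_state(1)[0] % 2**31) for x in child.spawn(4)]
        strain_a = mutate_strain(
            reference, strain_divergence, seed=s[0], lineage_id=f"pair{i}a"
        )
        strain_b = (
            strain_a
            if related
            else mutate_strain(
                reference, strain_divergence, seed=s[1], lineage_id=f"pair{i}b"
            )
        )
        pu_a, dt_a = simulate_pileup(
            strain_a, mean_depth, base_error_rate=base_error_rate, seed=s[2]
        )
        pu_b, dt_b = simulate_pileup(
            strain_b, mean_depth, base_error_rate=base_error_rate, seed=s[3]
        )
        pairs.append(
            LabelledPair("related" if related else "unrelated", pu_a, pu_b, dt_a, dt_b)
        )
    return pairs


def simulate_abundance_table(
    n_groups: int = 5,
    samples_per_group: int = 5,
    n_taxa: int = 40,
    between_group_effect: float = 0.0,
    seed: int = 0,
    total_reads: int = 50_000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Grouped taxa count tables from log-normal compositions.

    Each taxon has a baseline log-abundance; each group adds a
    taxon-specific offset of scale ``between_group_effect``; each
    sample adds independent log-normal noise and is multinomially
    sequenced to ``total_reads``.  With effect 0 the samples are
    exchangeable across groups (a null community).
    Returns (counts DataFrame samples x taxa, group labels Series).
    """
    if n_groups < 2 or samples_per_group < 2:
        raise ValueError("need at least 2 groups of at least 2 samples")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.0, size=n_taxa)
    group_offsets = rng.normal(0.0, between_group_effect, size=(n_groups, n_taxa))
    rows, labels, index = [], [], []
    for g in range(n_groups):
        for s in range(samples_per_group):
            logab = base + group_offsets[g] + rng.normal(0.0, 0.3, size=n_taxa)
            p = np.exp(logab)
            p /= p.sum()
            rows.append(rng.multinomial(total_reads, p))
            labels.append(f"group{g + 1}")
            index.append(f"group{g + 1}_s{s + 1}")
    taxa = [f"taxon{t + 1:03d}" for t in range(n_taxa)]
    table = pd.DataFrame(np.array(rows), index=index, columns=taxa)
    return table, pd.Series(labels, index=index, name="group")


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------


def write_fasta(references: list[ReferenceSequence] | dict[str, ReferenceSequence], path) -> None:
    refs = list(references.values()) if isinstance(references, dict) else references
    with open(path, "w") as fh:
        for ref in refs:
            fh.write(f">{ref.species_id} {ref.name}\n")
            for i in range(0, ref.length, 80):
                fh.write(ref.sequence[i : i + 80] + "\n")


def write_sam(
    records: list[AlignmentRecord],
    references: list[ReferenceSequence] | dict[str, ReferenceSequence],
    path,
) -> None:
    """Write alignment records as plain-text SAM via pysam."""
    import pysam

    refs = list(references.values()) if isinstance(references, dict) else references
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.species_id, "LN": r.length} for r in refs],
    }
    tid = {r.species_id: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.sequence or ""
            a.reference_id = tid[rec.species_id]
            a.reference_start = rec.pos - 1
            a.mapping_quality = 60
            a.cigarstring = f"{rec.aligned_length}M"
            a.is_secondary = rec.is_secondary
            a.is_supplementary = rec.is_supplementary
            a.set_tag("NM", rec.edit_distance)
            out.write(a)


def write_truth_tsv(dataset: CohortDataset, path) -> None:
    rows = [
        {"sample_a": a, "sample_b": b, "species": sp, "label": label}
        for ((a, b), sp), label in sorted(dataset.truth_labels.items())
    ]
    pd.DataFrame(rows, columns=["sample_a", "sample_b", "species", "label"]).to_csv(
        path, sep="\t", index=False
    )
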