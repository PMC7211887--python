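"""Reading standard formats and building consensus SNV profiles.

The alignment filter drops multi-mapped (secondary/supplementary)
records and records whose percent identity, computed as
``(aligned_length - edit_distance) / aligned_length`` from the NM tag,
falls below 90%.  Retained reads are piled up into per-position allele
counts, from which a naive consensus caller derives each sample's SNV
profile; multi-sample VCFs produced by external callers can be
consumed instead through :func:`read_vcf`.

The consensus caller (min depth 5, min alternate-allele fraction 0.8,
both configurable) is a deliberately simple stand-in for a full
variant-calling workflow and is documented as such; positions where
the reference base is N are never callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BASE_INDEX,
    BASES,
    AlignmentRecord,
    DepthTrack,
    Pileup,
    ReferenceSequence,
    SNVProfile,
)

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_ALLELE_FRACTION = 0.8


def read_fasta(path, mask_ambiguous: bool = True) -> list[ReferenceSequence]:
    """Read reference genomes from FASTA.

    Sequences are uppercased.  Ambiguity codes other than N are either
    masked to N (``mask_ambiguous``, the default) or rejected.
    """
    refs: list[ReferenceSequence] = []
    seen: set[str] = set()
    name = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        bad = set(seq) - set(BASES + "N")
        if bad:
            if not mask_ambiguous:
                raise ValueError(f"{name}: non-ACGTN characters {sorted(bad)}")
            table = str.maketrans({c: "N" for c in bad})
            seq = seq.translate(table)
        sid = name.split()[0]
        if sid in seen:
            raise ValueError(f"duplicate FASTA id {sid!r}")
        seen.add(sid)
        refs.append(ReferenceSequence(sid, name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, chunks = line[1:].strip(), []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
    flush()
    if not refs:
        raise ValueError("empty FASTA")
    return refs


def read_sam(path) -> list[AlignmentRecord]:
    """Parse a SAM file into alignment records (unmapped reads skipped)."""
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for r in fh:
            if r.is_unmapped:
                continue
            nm = int(r.get_tag("NM")) if r.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id=r.query_name,
                    species_id=r.reference_name,
                    pos=r.reference_start + 1,
                    aligned_length=r.query_alignment_length,
                    edit_distance=nm,
                    is_secondary=r.is_secondary,
                    is_supplementary=r.is_supplementary,
                    sequence=r.query_alignment_sequence,
                )
            )
    return records


@dataclass
class FilterTally:
    retained: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def bump(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def filter_alignments(
    records: list[AlignmentRecord], min_identity: float = DEFAULT_MIN_IDENTITY
) -> tuple[list[AlignmentRecord], FilterTally]:
    """Drop multi-mapped and low-identity records.

    Rejection reasons: ``multi-mapped`` (secondary or supplementary
    flag), ``low-identity`` (< min_identity), ``degenerate`` (zero
    aligned length).
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must lie in (0, 1]")
    kept: list[AlignmentRecord] = []
    tally = FilterTally()
    for rec in records:
        if rec.is_secondary or rec.is_supplementary:
            tally.bump("multi-mapped")
        elif rec.aligned_length <= 0:
            tally.bump("degenerate")
        elif rec.identity < min_identity:
            tally.bump("low-identity")
        else:
            kept.append(rec)
    tally.retained = len(kept)
    return kept, tally


def pileup(
    records: list[AlignmentRecord], reference: ReferenceSequence
) -> tuple[Pileup, DepthTrack]:
    """Stack filtered, ungapped records into per-position allele counts."""
    L = reference.length
    counts = np.zeros((L, 4), dtype=np.int64)
    for rec in records:
        if rec.species_id != reference.species_id:
            raise ValueError(
                f"record {rec.read_id} maps to {rec.species_id}, not "
                f"{reference.species_id}"
            )
        if rec.end > L:
            raise ValueError(f"record {rec.read_id} extends past reference end")
        if rec.sequence is None or len(rec.sequence) != rec.aligned_length:
            raise ValueError(f"record {rec.read_id} lacks a usable sequence")
        start0 = rec.pos - 1
        for i, base in enumerate(rec.sequence):
            idx = BASE_INDEX.get(base)
            if idx is not None:
                counts[start0 + i, idx] += 1
    pu = Pileup(reference.species_id, counts)
    return pu, pu.depth_track()


def call_consensus_snvs(
    pileup: Pileup,
    reference: ReferenceSequence,
    sample_id: str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_fraction: float = DEFAULT_MIN_ALLELE_FRACTION,
) -> SNVProfile:
    """Call consensus SNVs from allele counts.

    A position is called variant iff its depth is at least
    ``min_depth`` and the most frequent non-reference base reaches
    ``min_allele_fraction`` of the depth.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be at least 1")
    if not 0.5 < min_allele_fraction <= 1:
        raise ValueError("min_allele_fraction must lie in (0.5, 1]")
    if pileup.length != reference.length:
        raise ValueError("pileup and reference lengths differ")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    ref_idx = reference.base_indices()
    nonref = counts.copy()
    pos_idx = np.arange(reference.length)
    valid = ref_idx >= 0
    nonref[pos_idx[valid], ref_idx[valid]] = -1
    best = nonref.argmax(axis=1)
    best_count = nonref[pos_idx, best]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
    called = (
        valid
        & (depth >= min_depth)
        & (best_count > 0)
        & (frac >= min_allele_fraction - 1e-12)
    )
    calls = {int(p) + 1: BASES[int(best[p])] for p in np.nonzero(called)[0]}
    depth_at = {int(p) + 1: int(depth[p]) for p in np.nonzero(called)[0]}
    return SNVProfile(sample_id, reference.species_id, calls, depth_at)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    profiles: list[SNVProfile],
    references: dict[str, ReferenceSequence],
    path,
) -> None:
    """Write SNV profiles as a multi-sample VCF 4.2 (biallelic SNVs).

    Sites where different samples carry different alternate bases are
    emitted as one record per alternate allele; samples not carrying a
    record's allele are written as missing (uncalled), so the round
    trip through :func:`read_vcf` is lossless for the calls.
    """
    sample_ids = sorted({p.sample_id for p in profiles})
    by_sample_species: dict[tuple[str, str], SNVProfile] = {
        (p.sample_id, p.species_id): p for p in profiles
    }
    species_ids = sorted({p.species_id for p in profiles})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for sp in species_ids:
            fh.write(f"##contig=<ID={sp},length={references[sp].length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for sp in species_ids:
            ref = references[sp]
            sites: dict[tuple[int, str], list[str]] = {}
            for sid in sample_ids:
                prof = by_sample_species.get((sid, sp))
                if prof is None:
                    continue
                for pos, alt in prof.calls.items():
                    sites.setdefault((pos, alt), []).append(sid)
            for (pos, alt), carriers in sorted(sites.items()):
                ref_base = ref.sequence[pos - 1]
                cells = []
                for sid in sample_ids:
                    if sid in carriers:
                        dp = by_sample_species[(sid, sp)].depth_at_call.get(pos, 0)
                        cells.append(f"1/1:{dp}")
                    else:
                        cells.append("./.:.")
                fh.write(
                    f"{sp}\t{pos}\t.\t{ref_base}\t{alt}\t.\tPASS\t.\tGT:DP\t"
                    + "\t".join(cells)
                    + "\n"
                )


def read_vcf(path, known_contigs: set[str] | None = None) -> dict[str, dict[str, SNVProfile]]:
    """Read a multi-sample VCF into per-sample, per-species profiles.

    Homozygous-alternate genotypes become calls; missing genotypes are
    uncalled.  Heterozygous genotypes are treated as uncalled (the
    consensus model carries one allele per sample).  Returns
    ``{sample_id: {species_id: SNVProfile}}``.
    """
    import pysam

    out: dict[str, dict[str, SNVProfile]] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for sid in samples:
            out[sid] = {}
        for rec in vf:
            if known_contigs is not None and rec.chrom not in known_contigs:
                raise ValueError(f"unknown contig {rec.chrom!r} in VCF")
            if rec.alts is None or len(rec.alts) != 1 or len(rec.alts[0]) != 1:
                continue  # biallelic SNVs only
            alt = rec.alts[0]
            for sid in samples:
                call = rec.samples[sid]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if not all(a == 1 for a in gt):
                    continue
                prof = out[sid].setdefault(rec.chrom, SNVProfile(sid, rec.chrom))
                prof.calls[rec.pos] = alt
                dp = call.get("DP")
                if dp is not None:
                    prof.depth_at_call[rec.pos] = int(dp)
    return out


# ---------------------------------------------------------------------------
# depth TSV
# ---------------------------------------------------------------------------


def write_depth_tsv(tracks: list[DepthTrack], path) -> None:
    """Write depth tracks as TSV (species, pos, depth); zeros omitted."""
    with open(path, "w") as fh:
        fh.write("species\tpos\tdepth\n")
        for track in tracks:
            nz = np.nonzero(track.depth)[0]
            for p in nz:
                fh.write(f"{track.species_id}\t{p + 1}\t{track.depth[p]}\n")


def read_depth_tsv(path, reference_length: int, species_id: str | None = None) -> DepthTrack:
    """Read one species' depth track; absent positions default to 0."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["species", "pos", "depth"])
    if df.empty:
        if species_id is None:
            raise ValueError("empty depth TSV and no species_id given")
        return DepthTrack(species_id, np.zeros(reference_length, dtype=np.int64))
    if species_id is not None:
        df = df[df["species"] == species_id]
    else:
        species = df["species"].unique()
        if len(species) > 1:
            raise ValueError("depth TSV holds several species; pass species_id")
        species_id = str(species[0]) if len(species) else None
    depth = np.zeros(reference_length, dtype=np.int64)
    if not df.empty:
        if (df["depth"] < 0).any():
            raise ValueError("negative depth in TSV")
        if (df["pos"] < 1).any() or (df["pos"] > reference_length).any():
            raise ValueError("depth TSV position outside the reference")
        depth[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
    return DepthTrack(species_id or "unknown", depth)
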