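"""Translation-based loss-of-function (LoF) allele calling.

Instead of labelling individual variants, each ecotype's full set of coding
variants in a gene is spliced into the reference CDS, the result is
translated, and the allele is called non-functional when at least 10% of the
reference protein is lost to a late start codon and/or premature truncation.
Joint application of variants means compensatory pairs (e.g. +1 bp and +2 bp
frameshifts that restore frame between them) are honoured and do not produce
false LoF calls.

The filter cascade, applied per gene:

1. single predicted gene model (exactly one transcript);
2. >= 5% carrier frequency of putative frameshift / premature-stop /
   start-loss variants and < 5% missing allele calls;
3. translation of every carrier's coding sequence and classification of the
   allele as LoF iff >= 10% of the reference protein is lost;
4. a re-applied >= 5% global LoF allele frequency filter on the translated
   calls.

Surviving genes form the binary functional-state matrix (functional 0 / LoF
1 / missing) used by the association scan, and per-gene unique-allele
summaries proxy independent molecular origins of LoF by distinct truncated
protein lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

LOF_CONSEQUENCES = frozenset({"premature_stop", "frameshift", "start_loss"})

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class LofCallerError(ValueError):
    """Raised for malformed gene models or inconsistent variant input."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide string with the standard code ('*' = stop)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """Single-transcript gene model with its spliced reference CDS.

    ``cds_intervals`` are genomic, 1-based inclusive, sorted ascending; the
    CDS string is in transcript orientation (reverse-complemented for minus
    strand genes).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list
    ref_cds: str
    ref_protein_len: int = field(init=False)

    def __post_init__(self):
        length = sum(e - s + 1 for s, e in self.cds_intervals)
        if length != len(self.ref_cds):
            raise LofCallerError(
                f"{self.gene_id}: CDS intervals span {length} nt but FASTA "
                f"sequence is {len(self.ref_cds)} nt"
            )
        if len(self.ref_cds) % 3 != 0:
            raise LofCallerError(f"{self.gene_id}: CDS length not divisible by 3")
        prev_end = 0
        for s, e in self.cds_intervals:
            if s <= prev_end:
                raise LofCallerError(f"{self.gene_id}: CDS intervals overlap or unsorted")
            prev_end = e
        self.ref_protein_len = _protein_length(self.ref_cds)

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based CDS offset of genomic position ``pos``, or None outside CDS."""
        offset = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= pos <= e:
                    return offset + (pos - s)
                offset += e - s + 1
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= pos <= e:
                    return offset + (e - pos)
                offset += e - s + 1
        return None

    def map_allele(self, pos: int, ref: str, alt: str):
        """Map a genomic REF/ALT pair into CDS space.

        Returns ``(cds_offset, cds_ref, cds_alt)`` with alleles in transcript
        orientation, or None when the REF span is not fully inside one CDS
        interval (noncoding or junction-spanning; the latter is outside this
        caller's scope).
        """
        end = pos + len(ref) - 1
        for s, e in self.cds_intervals:
            if s <= pos and end <= e:
                if self.strand == "+":
                    return self.genomic_to_cds(pos), ref, alt
                return self.genomic_to_cds(end), _revcomp(ref), _revcomp(alt)
        return None


def load_gene_models(gff3_path, cds_fasta_path) -> tuple[dict, dict]:
    """Parse GFF3 + CDS FASTA into single-transcript :class:`GeneModel` objects.

    Genes with more than one mRNA are dropped (exon-skipping could mask LoF
    there); genes whose CDS interval span disagrees with the FASTA sequence
    length are skipped with a log entry.  Returns ``(models, report)`` where
    report counts genes retained / multi-transcript / parse-failed.
    """
    import gffutils
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    report = {"retained": 0, "multi_transcript": 0, "parse_error": 0, "no_sequence": 0}
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) != 1:
            report["multi_transcript"] += 1
            continue
        cds = sorted(
            db.children(mrnas[0], featuretype="CDS"), key=lambda f: f.start
        )
        seq = seqs.get(gene_id)
        if seq is None:
            report["no_sequence"] += 1
            logger.warning("%s: no CDS sequence in FASTA, skipped", gene_id)
            continue
        try:
            models[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_intervals=[(f.start, f.end) for f in cds],
                ref_cds=seq,
            )
            report["retained"] += 1
        except LofCallerError as err:
            report["parse_error"] += 1
            logger.warning("skipping gene: %s", err)
    return models, report


# ---------------------------------------------------------------------------
# Variants


@dataclass
class Variant:
    """One normalized ALT allele at a genomic position (VCF-style, 1-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def normalized(self, context: str | None = None) -> "Variant":
        """Trim shared suffix/prefix bases (keeping a 1 nt anchor for indels)."""
        pos, ref, alt = self.pos, self.ref, self.alt
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return Variant(self.chrom, pos, ref, alt)


def annotate_consequence(variant: Variant, model: GeneModel) -> str:
    """Predicted consequence of a single variant on a gene model.

    Labels: ``premature_stop``, ``frameshift``, ``start_loss``, ``inframe``,
    ``synonymous``, ``missense``, ``noncoding``.
    """
    for base in variant.ref + variant.alt:
        if base not in "ACGT":
            raise LofCallerError(
                f"non-ACGT allele {variant.ref}>{variant.alt} at {variant.chrom}:{variant.pos}"
            )
    v = variant.normalized()
    mapped = model.map_allele(v.pos, v.ref, v.alt)
    if mapped is None:
        return "noncoding"
    offset, cds_ref, cds_alt = mapped
    if len(cds_ref) != len(cds_alt):
        return "frameshift" if abs(len(cds_ref) - len(cds_alt)) % 3 else "inframe"
    if offset < 3:  # substitution touches the start codon
        alt_start = (model.ref_cds[:offset] + cds_alt + model.ref_cds[offset + len(cds_ref):])[:3]
        if alt_start != START_CODON:
            return "start_loss"
    codon_start = (offset // 3) * 3
    codon_end = ((offset + len(cds_ref) - 1) // 3 + 1) * 3
    ref_codons = model.ref_cds[codon_start:codon_end]
    alt_seq = model.ref_cds[:offset] + cds_alt + model.ref_cds[offset + len(cds_ref):]
    alt_codons = alt_seq[codon_start:codon_end]
    ref_aa = translate(ref_codons)
    alt_aa = translate(alt_codons)
    if "*" in alt_aa and "*" not in ref_aa:
        return "premature_stop"
    return "synonymous" if alt_aa == ref_aa else "missense"


@dataclass
class ProteinPrediction:
    """Predicted protein for one ecotype x gene after applying its variants."""

    ecotype: str
    gene_id: str
    predicted_len: int
    reference_len: int
    truncation_fraction: float
    mechanism: str  # premature_stop | frameshift | start_loss | none


def _protein_length(cds: str, start_offset: int = 0) -> int:
    """Amino acids from the first start to the first stop codon.

    If translation never reaches a stop (e.g. a frameshift removed it) the
    count runs to the end of the available sequence.
    """
    aa = translate(cds[start_offset:])
    stop = aa.find("*")
    return len(aa) if stop == -1 else stop


def _find_inframe_start(cds: str) -> int | None:
    for off in range(0, len(cds) - 2, 3):
        if cds[off : off + 3] == START_CODON:
            return off
    return None


def apply_variants_and_translate(
    ecotype: str,
    gene: GeneModel,
    variants: list,
) -> ProteinPrediction:
    """Splice all of one ecotype's variants into the CDS jointly and translate.

    Variants are normalized, mapped into CDS coordinates and applied from the
    3' end so earlier offsets stay valid.  On start-codon disruption the first
    in-frame downstream ATG rescues translation ("late start codon"); with no
    rescue ATG the whole protein counts as lost.  The truncation fraction is
    ``max(0, 1 - predicted / reference)`` protein length.
    """
    mapped = []
    for variant in variants:
        v = variant.normalized()
        m = gene.map_allele(v.pos, v.ref, v.alt)
        if m is None:
            continue
        offset, cds_ref, cds_alt = m
        found = gene.ref_cds[offset : offset + len(cds_ref)]
        if found != cds_ref:
            raise LofCallerError(
                f"{gene.gene_id}: REF mismatch at CDS offset {offset} "
                f"(VCF {cds_ref!r} vs reference {found!r})"
            )
        mapped.append((offset, cds_ref, cds_alt, v))
    mapped.sort(key=lambda t: t[0])
    for (o1, r1, _, v1), (o2, _, _, v2) in zip(mapped, mapped[1:]):
        if o1 + len(r1) > o2:
            raise LofCallerError(
                f"{gene.gene_id}/{ecotype}: overlapping ALT alleles at "
                f"{v1.chrom}:{v1.pos} and {v2.chrom}:{v2.pos}"
            )
    seq = gene.ref_cds
    net_indel = 0
    for offset, cds_ref, cds_alt, _ in reversed(mapped):
        seq = seq[:offset] + cds_alt + seq[offset + len(cds_ref):]
        net_indel += len(cds_alt) - len(cds_ref)

    ref_len = gene.ref_protein_len
    start_lost = seq[:3] != START_CODON
    if start_lost:
        rescue = _find_inframe_start(seq)
        pred_len = _protein_length(seq, rescue) if rescue is not None else 0
        mechanism = "start_loss"
    else:
        pred_len = _protein_length(seq)
        aa = translate(seq)
        stop_idx = aa.find("*")
        stop_is_premature = stop_idx != -1 and stop_idx < len(seq) // 3 - 1
        if not mapped or pred_len >= ref_len:
            mechanism = "none"
        elif net_indel % 3 != 0:
            mechanism = "frameshift"
        elif stop_is_premature:
            mechanism = "premature_stop"
        else:
            mechanism = "none"  # in-frame shortening ends at the natural stop
    fraction = max(0.0, 1.0 - pred_len / ref_len) if ref_len else 0.0
    if mechanism == "start_loss" and fraction == 0.0:
        mechanism = "none"  # rescue start recovered the full protein
    return ProteinPrediction(
        ecotype=ecotype,
        gene_id=gene.gene_id,
        predicted_len=pred_len,
        reference_len=ref_len,
        truncation_fraction=fraction,
        mechanism=mechanism,
    )


def classify_allele(prediction: ProteinPrediction, loss_min: float = 0.10) -> int:
    """1 (LoF) iff at least ``loss_min`` of the reference protein is lost."""
    return int(prediction.truncation_fraction >= loss_min)


# ---------------------------------------------------------------------------
# VCF loading


@dataclass
class GeneVariantCalls:
    """All calls in one gene: variants, consequences, genotype matrix.

    ``genotypes`` is (n_variants, n_ecotypes) with 0 ref / 1 alt / -1 missing.
    """

    gene_id: str
    variants: list
    consequences: list
    genotypes: np.ndarray


def load_variant_calls(
    vcf_path, models: dict, het_policy: str = "missing"
) -> tuple[dict, list]:
    """Read a VCF once and bucket consequence-annotated calls per gene.

    Ecotypes are haploid/inbred; heterozygous diploid calls are treated as
    missing by default (``het_policy='alt'`` counts them as carriers).
    Multi-allelic records are split per ALT.
    """
    from cyvcf2 import VCF

    by_chrom: dict[str, list[GeneModel]] = {}
    for model in models.values():
        by_chrom.setdefault(model.chrom, []).append(model)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    buckets: dict[str, GeneVariantCalls] = {
        g: GeneVariantCalls(g, [], [], None) for g in models
    }
    geno_lists: dict[str, list] = {g: [] for g in models}
    for rec in vcf:
        gts = rec.genotypes  # [allele(, allele2), phased] per sample
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            calls = np.empty(len(samples), dtype=np.int8)
            for i, gt in enumerate(gts):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    calls[i] = -1
                elif len(set(alleles)) > 1:
                    calls[i] = -1 if het_policy == "missing" else int(alt_idx in alleles)
                else:
                    calls[i] = int(alleles[0] == alt_idx)
            variant = Variant(rec.CHROM, rec.POS, rec.REF, alt)
            for model in by_chrom.get(rec.CHROM, []):
                span = (model.cds_intervals[0][0], model.cds_intervals[-1][1])
                if not (span[0] - 1 <= rec.POS <= span[1]):
                    continue
                try:
                    cons = annotate_consequence(variant, model)
                except LofCallerError as err:
                    logger.warning("record skipped: %s", err)
                    continue
                if cons == "noncoding":
                    continue
                buckets[model.gene_id].variants.append(variant)
                buckets[model.gene_id].consequences.append(cons)
                geno_lists[model.gene_id].append(calls)
    for gene_id, calls in buckets.items():
        calls.genotypes = (
            np.array(geno_lists[gene_id], dtype=np.int8)
            if geno_lists[gene_id]
            else np.empty((0, len(samples)), dtype=np.int8)
        )
    return buckets, samples


def prefilter_genes(
    calls: dict,
    n_ecotypes: int,
    freq_min: float = 0.05,
    missing_max: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Frequency/missingness prefilter on putative-LoF variant calls.

    A gene passes when the carrier frequency of frameshift / premature-stop /
    start-loss variants is at least ``freq_min`` ("at least 5%") and the
    fraction of ecotypes with a missing call at any such variant is strictly
    below ``missing_max``.  Carrier frequency counts ecotypes carrying >= 1
    putative-LoF variant, computed among non-missing ecotypes.
    """
    rows = []
    retained = []
    for gene_id, gvc in calls.items():
        lof_rows = [i for i, c in enumerate(gvc.consequences) if c in LOF_CONSEQUENCES]
        if not lof_rows:
            rows.append((gene_id, 0.0, 0.0, False))
            continue
        sub = gvc.genotypes[lof_rows]
        missing = (sub == -1).any(axis=0)
        carrier = (sub == 1).any(axis=0) & ~missing
        n_obs = int((~missing).sum())
        carrier_freq = carrier.sum() / n_obs if n_obs else 0.0
        missing_rate = missing.sum() / n_ecotypes
        keep = carrier_freq >= freq_min and missing_rate < missing_max
        rows.append((gene_id, carrier_freq, missing_rate, keep))
        if keep:
            retained.append(gene_id)
    report = pd.DataFrame(
        rows, columns=["gene_id", "carrier_freq", "missing_rate", "retained"]
    ).set_index("gene_id")
    return retained, report


# ---------------------------------------------------------------------------
# Matrix construction


@dataclass
class FunctionalStateMatrix:
    """Binary functional-state calls with per-gene summaries.

    ``states``: DataFrame ecotypes x genes with 0 (functional), 1 (LoF) or
    NaN (missing).  ``predictions``: long DataFrame of per-carrier protein
    predictions (ecotype, gene_id, predicted_len, reference_len,
    truncation_fraction, mechanism).  ``gene_summary``: per-gene LoF
    frequency (among non-missing) and missing rate.
    """

    states: pd.DataFrame
    predictions: pd.DataFrame
    gene_summary: pd.DataFrame

    def to_csv(self, states_path, summary_path=None) -> None:
        self.states.to_csv(states_path, index_label="ecotype")
        if summary_path is not None:
            self.gene_summary.to_csv(summary_path, index_label="gene_id")


def build_matrix(
    models: dict,
    calls: dict,
    samples: list,
    gene_ids: list,
    loss_min: float = 0.10,
    freq_min: float = 0.05,
) -> FunctionalStateMatrix:
    """Translate every carrier, classify, and apply the final frequency filter.

    For each candidate gene, ecotypes with any missing call at the gene's
    putative-LoF variants are coded missing; all others have their full
    variant complement spliced and translated.  Genes whose translated LoF
    frequency (among non-missing ecotypes) falls below ``freq_min`` are
    dropped, re-applying the 5% rule after compensation and the >= 10%-lost
    rule have had their say.
    """
    n = len(samples)
    state_cols, pred_rows, summary_rows = {}, [], []
    for gene_id in gene_ids:
        model = models[gene_id]
        gvc = calls[gene_id]
        lof_rows = [i for i, c in enumerate(gvc.consequences) if c in LOF_CONSEQUENCES]
        missing = (
            (gvc.genotypes[lof_rows] == -1).any(axis=0)
            if lof_rows
            else np.zeros(n, dtype=bool)
        )
        states = np.zeros(n, dtype=float)
        states[missing] = np.nan
        for i, ecotype in enumerate(samples):
            if missing[i]:
                continue
            var_idx = [
                j for j in range(len(gvc.variants)) if gvc.genotypes[j, i] == 1
            ]
            if not var_idx:
                continue
            pred = apply_variants_and_translate(
                ecotype, model, [gvc.variants[j] for j in var_idx]
            )
            call = classify_allele(pred, loss_min)
            states[i] = call
            pred_rows.append(
                (
                    ecotype,
                    gene_id,
                    pred.predicted_len,
                    pred.reference_len,
                    pred.truncation_fraction,
                    pred.mechanism,
                    call,
                )
            )
        n_obs = int(np.isfinite(states).sum())
        lof_freq = np.nansum(states) / n_obs if n_obs else 0.0
        retained = lof_freq >= freq_min
        summary_rows.append(
            (gene_id, lof_freq, missing.sum() / n, retained)
        )
        if retained:
            state_cols[gene_id] = states
    states_df = pd.DataFrame(state_cols, index=pd.Index(samples, name="ecotype"))
    predictions = pd.DataFrame(
        pred_rows,
        columns=[
            "ecotype",
            "gene_id",
            "predicted_len",
            "reference_len",
            "truncation_fraction",
            "mechanism",
            "is_lof",
        ],
    )
    summary = pd.DataFrame(
        summary_rows, columns=["gene_id", "lof_freq", "missing_rate", "retained"]
    ).set_index("gene_id")
    return FunctionalStateMatrix(
        states=states_df,
        predictions=predictions[predictions["gene_id"].isin(states_df.columns)],
        gene_summary=summary,
    )


def call_lof(
    vcf_path,
    gff3_path,
    cds_fasta_path,
    freq_min: float = 0.05,
    missing_max: float = 0.05,
    loss_min: float = 0.10,
    het_policy: str = "missing",
) -> FunctionalStateMatrix:
    """Full pipeline: gene models -> prefilter -> translation -> matrix."""
    models, _ = load_gene_models(gff3_path, cds_fasta_path)
    calls, samples = load_variant_calls(vcf_path, models, het_policy=het_policy)
    candidates, _ = prefilter_genes(calls, len(samples), freq_min, missing_max)
    return build_matrix(models, calls, samples, candidates, loss_min, freq_min)


def count_unique_alleles(matrix: FunctionalStateMatrix) -> pd.DataFrame:
    """Per-gene unique-LoF-allele summary by distinct predicted protein length.

    Distinct truncated protein lengths among LoF carriers proxy independent
    molecular origins of loss-of-function.  Returns per gene: ``n_unique``
    allele count, global LoF frequency, and the mean frequency per specific
    allele (carriers of that length / non-missing ecotypes).
    """
    rows = []
    lof = matrix.predictions[matrix.predictions["is_lof"] == 1]
    for gene_id in matrix.states.columns:
        states = matrix.states[gene_id]
        n_obs = int(states.notna().sum())
        lengths = lof.loc[lof["gene_id"] == gene_id, "predicted_len"]
        counts = lengths.value_counts()
        rows.append(
            (
                gene_id,
                len(counts),
                states.sum() / n_obs if n_obs else 0.0,
                (counts / n_obs).mean() if len(counts) else 0.0,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_unique", "lof_freq", "mean_allele_freq"]
    ).set_index("gene_id")
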