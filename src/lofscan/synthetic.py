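"""Synthetic study system: drought rasters, genomes, phenotypes, experiments.

Generates every input the pipeline consumes — weekly VHI rasters with a
spatial spring-vs-summer drought gradient, a panel of inbred ecotypes with
cluster population structure, per-gene LoF alleles whose frequency follows a
logistic model in the drought-timing index, flowering-time phenotypes built
from per-allele effects, ortholog codon alignments with planted
polymorphism/divergence counts, and a shelf-stratified knockout experiment —
together with the ground truth needed for parameter-recovery tests.

Ecotypes are haploid/fully inbred (selfing), so every call is a single
allele and the functional/non-functional coding is binary.  Each gene's LoF
carriers are split among 1-5 distinct molecular alleles (premature-stop
SNPs, frameshift indels, start-loss SNPs at distinct positions, hence
distinct truncated protein lengths), emulating parallel molecular origins
of loss-of-function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .climatology import VhiGrid

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study system.

    Defaults mirror the study conditions the pipeline targets: a 1/3 day
    flowering-time increase per LoF allele, a 59-line knockout experiment
    with 10 replicates per line and 30 wild-type replicates, and 34 years of
    weekly VHI on a 0-100 scale.
    """

    seed: int = 0
    n_ecotypes: int = 500
    n_genes: int = 200
    n_causal_spring_late: int = 30
    n_causal_summer_early: int = 10
    grid_shape: tuple = (20, 30)
    n_years: int = 34
    clusters: int = 3
    effect_per_lof_day: float = 1.0 / 3.0
    env_logit_slope: float = 1.0
    noise_sd_days: float = 3.0
    missing_rate: float = 0.0
    # raster structure
    spring_prob_range: tuple = (0.05, 0.45)
    summer_prob_range: tuple = (0.45, 0.05)
    fall_prob: float = 0.15
    winter_prob: float = 0.10
    water_fraction: float = 0.10
    lat0: float = 60.0
    lon0: float = 0.0
    cell: float = 1.0
    # population / genome structure
    n_background_markers: int = 400
    fst: float = 0.15
    cluster_logit_sd: float = 0.5
    cluster_days_sd: float = 2.0
    baseline_days: float = 60.0
    lof_freq_range: tuple = (0.08, 0.30)
    n_lowfreq_genes: int = 10
    lowfreq_target: float = 0.02
    causal_allele_range: tuple = (1, 2)
    null_allele_range: tuple = (1, 5)
    allele_skew: float = 1.5
    gene_len_range: tuple = (120, 300)  # codons incl. stop
    minus_strand_fraction: float = 0.3
    two_exon_fraction: float = 0.4
    neutral_variant_freq: float = 0.10
    n_multi_transcript_decoys: int = 2
    # ortholog alignments
    n_ingroup_aln: int = 6
    mk_pn_assoc: float = 6.0
    mk_pn_null: float = 3.0
    mk_ps: float = 3.0
    mk_dn_assoc: float = 6.0
    mk_dn_null: float = 3.0
    mk_ds: float = 4.0
    gap_codon_rate: float = 0.3
    # knockout experiment
    knockout_lines: int = 59
    reps_per_line: int = 10
    wt_reps: int = 30
    n_negative_knockout_lines: int = 2
    knockout_effect_range: tuple = (1.0, 3.0)
    knockout_negative_effect: float = -0.5
    n_shelves: int = 4
    trays_per_shelf: int = 5
    shelf_sd_days: float = 1.0
    tray_sd_days: float = 0.5
    experiment_noise_sd: float = 0.7
    wild_type: str = "Col-0"

    def __post_init__(self):
        positive = {
            "n_ecotypes": self.n_ecotypes,
            "n_genes": self.n_genes,
            "n_years": self.n_years,
            "clusters": self.clusters,
            "knockout_lines": self.knockout_lines,
            "reps_per_line": self.reps_per_line,
            "wt_reps": self.wt_reps,
            "n_shelves": self.n_shelves,
            "trays_per_shelf": self.trays_per_shelf,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if min(self.grid_shape) <= 0:
            raise ConfigError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.n_causal_spring_late + self.n_causal_summer_early > self.n_genes:
            raise ConfigError("causal gene counts exceed n_genes")
        if not 0 <= self.missing_rate < 0.05:
            raise ConfigError("missing_rate must lie in [0, 0.05)")
        if self.n_causal_spring_late < 0 or self.n_causal_summer_early < 0:
            raise ConfigError("causal gene counts must be non-negative")


@dataclass
class GroundTruth:
    """Simulation ground truth used as the recovery oracle in tests."""

    gene_class: dict  # gene -> spring_late | summer_early | null
    effect_days: dict  # gene -> per-allele flowering effect
    env_slope: dict  # gene -> logit slope on drought-timing index
    cluster_labels: pd.Series  # ecotype -> cluster
    line_effects: dict = field(default_factory=dict)  # knockout line -> days

    def to_json(self, path) -> None:
        payload = {
            "gene_class": self.gene_class,
            "effect_days": self.effect_days,
            "env_slope": self.env_slope,
            "cluster_labels": {k: int(v) for k, v in self.cluster_labels.items()},
            "line_effects": self.line_effects,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# VHI raster


def simulate_vhi_grid(config: SimulationConfig) -> VhiGrid:
    """Weekly VHI raster with a west-east spring/summer drought gradient.

    Each pixel has fixed seasonal drought probabilities: the spring
    probability rises across columns while the summer probability falls, so
    the drought-timing index increases monotonically west to east.  Weekly
    VHI is drawn uniform on [0, 40) in drought weeks and [40, 100] in
    non-drought weeks.  A random ``water_fraction`` of pixels is flagged
    water and carries no values.  The true per-pixel seasonal probabilities
    are attached as ``grid.true_seasonal_probs`` for recovery tests.
    """
    rows, cols = config.grid_shape
    rng = np.random.default_rng([config.seed, 11])
    frac = np.linspace(0.0, 1.0, cols)[None, :].repeat(rows, axis=0)
    p_spring = config.spring_prob_range[0] + frac * (
        config.spring_prob_range[1] - config.spring_prob_range[0]
    )
    p_summer = config.summer_prob_range[0] + frac * (
        config.summer_prob_range[1] - config.summer_prob_range[0]
    )
    probs = {
        "spring": p_spring,
        "summer": p_summer,
        "fall": np.full((rows, cols), config.fall_prob),
        "winter": np.full((rows, cols), config.winter_prob),
    }
    from .climatology import SeasonCalendar

    calendar = SeasonCalendar()
    week_prob = np.zeros((rows, cols, 52))
    for w in range(1, 53):
        week_prob[..., w - 1] = probs[calendar.season_of(w)]
    shape = (rows, cols, config.n_years, 52)
    drought = rng.random(shape) < week_prob[:, :, None, :]
    values = np.where(
        drought, rng.uniform(0, 40, shape), rng.uniform(40, 100, shape)
    )
    # drought weeks must satisfy VHI < 40 strictly
    values = np.clip(values, 0, 100)
    water = rng.random((rows, cols)) < config.water_fraction
    values[water] = np.nan
    grid = VhiGrid(
        values=values,
        water_mask=water,
        lat0=config.lat0,
        lon0=config.lon0,
        cell=config.cell,
        years=np.arange(1981, 1981 + config.n_years),
    )
    grid.true_seasonal_probs = probs
    return grid


# ---------------------------------------------------------------------------
# Gene/variant construction helpers (CDS-coordinate space)


def _random_codon(rng, forbid=("TAA", "TAG", "TGA", "ATG")):
    while True:
        codon = "".join(rng.choice(list(_BASES), 3))
        if codon not in forbid:
            return codon


def _splice_translate(cds: str, edits: list) -> int:
    """Protein length after applying (offset, ref, alt) edits to a CDS string.

    Local, direct oracle: splice, then translate from ATG (or the first
    in-frame downstream ATG on start loss) to the first stop.
    """
    seq = cds
    for offset, ref, alt in sorted(edits, key=lambda t: -t[0]):
        assert seq[offset : offset + len(ref)] == ref
        seq = seq[:offset] + alt + seq[offset + len(ref):]
    start = 0
    if seq[:3] != "ATG":
        start = None
        for off in range(0, len(seq) - 2, 3):
            if seq[off : off + 3] == "ATG":
                start = off
                break
        if start is None:
            return 0
    aa = str(Seq(seq[start : len(seq) - (len(seq) - start) % 3]).translate())
    stop = aa.find("*")
    return len(aa) if stop == -1 else stop


@dataclass
class _Allele:
    """One molecular LoF allele: a single CDS-space edit."""

    offset: int  # anchor offset of REF in CDS space
    ref: str
    alt: str
    protein_len: int
    kind: str


@dataclass
class _SimGene:
    gene_id: str
    strand: str
    cds: str  # reference CDS, transcript orientation
    intervals: list  # genomic (start, end), ascending
    alleles: list
    neutral: tuple | None  # (offset, ref, alt) synonymous
    gene_class: str
    target_freq: float


def _build_gene(
    rng, gene_id, gene_class, target_freq, cursor, config
) -> tuple["_SimGene", int]:
    """Construct one gene: reference CDS, exon layout, LoF allele edits.

    Premature-stop alleles plant a TAC codon mutable to TAA by SNP;
    start-loss alleles rely on a planted in-frame rescue ATG; frameshift
    indels are placed last, against the finalized sequence, and verified by
    direct splice+translation to truncate the protein.  Engineered
    shifted-frame stop elements guarantee frameshifts terminate early.  The
    whole gene is rebuilt on the rare occasions placement fails.
    """
    for _ in range(10):
        built = _try_build_gene(rng, gene_id, gene_class, target_freq, cursor, config)
        if built is not None:
            gene, end = built
            return gene, end + 500
    raise ConfigError(f"{gene_id}: could not construct a valid allele set")


def _try_build_gene(rng, gene_id, gene_class, target_freq, cursor, config):
    L = int(rng.integers(*config.gene_len_range))  # codons incl. terminal stop
    ref_len = L - 1
    strand = "-" if rng.random() < config.minus_strand_fraction else "+"
    causal = gene_class != "null"
    lo, hi = config.causal_allele_range if causal else config.null_allele_range
    n_alleles = int(rng.integers(lo, hi + 1))

    base_kinds = [
        "premature_stop",
        "frameshift_del",
        "start_loss",
        "frameshift_ins",
        "premature_stop",
    ]
    kinds = [base_kinds[i % len(base_kinds)] for i in range(n_alleles)]
    if strand == "-":
        # minus-strand genes carry SNP-type alleles only (unambiguous VCF anchoring)
        kinds = ["premature_stop" if k.startswith("frameshift") else k for k in kinds]

    # stop positions k give protein length exactly k; keep them distinct and
    # deep enough that >= 10% of the protein is lost
    k_min, k_max = max(4, int(0.15 * ref_len)), int(0.85 * ref_len)

    body = [_random_codon(rng) for _ in range(L - 2)]
    cds = ["ATG"] + body + ["TAA"]

    # exon layout
    total = 3 * L
    if rng.random() < config.two_exon_fraction and L > 40:
        split_codon = L // 2
        split = 3 * split_codon  # CDS offset of junction
        intron = 100
        intervals = [
            (cursor, cursor + split - 1),
            (cursor + split + intron, cursor + total + intron - 1),
        ]
        junction = range(split - 4, split + 4)
        if strand == "-":
            junction = range(total - split - 4, total - split + 4)
    else:
        intervals = [(cursor, cursor + total - 1)]
        junction = range(0)
    end = intervals[-1][1]
    junction_codons = {c // 3 for c in junction}

    planted: set[int] = set()
    rescue_len = 0
    if "start_loss" in kinds:
        # plant the rescue ATG; protein lost = j / ref_len
        j = int(rng.integers(int(0.15 * ref_len), int(0.4 * ref_len)))
        cds[j] = "ATG"
        rescue_len = ref_len - j
        planted.add(j)

    has_frameshift = any(k.startswith("frameshift") for k in kinds)
    if has_frameshift:
        # shifted-frame stop elements: CTA|GCA reads TAG one base late
        # (deletions); GCT|AAT reads TAA one base early (insertions)
        for i, e in enumerate(range(k_min + 2, k_max, 9)):
            if {e, e + 1} & (planted | junction_codons):
                continue
            cds[e], cds[e + 1] = ("CTA", "GCA") if i % 2 == 0 else ("GCT", "AAT")
            planted.update({e, e + 1})

    def free_codon(candidates):
        for k in candidates:
            if k not in planted and k not in junction_codons:
                return k
        return None

    alleles: list[_Allele] = []
    used_lengths = set()
    codon_pool = list(rng.permutation(np.arange(k_min, k_max)))
    for kind in (k for k in kinds if k in ("premature_stop", "start_loss")):
        if kind == "premature_stop":
            k = free_codon([c for c in codon_pool if c not in used_lengths])
            if k is None:
                return None
            codon_pool.remove(k)
            cds[k] = "TAC"
            planted.add(k)
            alleles.append(
                _Allele(offset=3 * k + 2, ref="C", alt="A", protein_len=k, kind=kind)
            )
            used_lengths.add(k)
        else:
            if rescue_len in used_lengths or rescue_len == 0:
                continue
            planted.add(0)
            alleles.append(
                _Allele(offset=1, ref="T", alt="C", protein_len=rescue_len, kind=kind)
            )
            used_lengths.add(rescue_len)

    # neutral synonymous variant: GGA -> GGT (both glycine)
    neutral = None
    spare = [k for k in range(2, L - 2) if k not in planted and k not in junction_codons]
    if spare:
        k = int(rng.choice(spare))
        cds[k] = "GGA"
        planted.add(k)
        neutral = (3 * k + 2, "A", "T")

    seq = "".join(cds)  # finalized: frameshift edits do not mutate it
    for kind in (k for k in kinds if k.startswith("frameshift")):
        placed = False
        for k in rng.permutation(np.arange(k_min, int(0.6 * ref_len))):
            k = int(k)
            if {k - 1, k} & (planted | junction_codons):
                continue
            o = 3 * k
            if kind == "frameshift_del":
                edit = (o - 1, seq[o - 1 : o + 1], seq[o - 1])
            else:
                edit = (o - 1, seq[o - 1], seq[o - 1] + "A")
            plen = _splice_translate(seq, [edit])
            if plen and plen not in used_lengths and plen <= 0.88 * ref_len:
                planted.add(k)
                alleles.append(
                    _Allele(
                        offset=edit[0], ref=edit[1], alt=edit[2], protein_len=plen, kind=kind
                    )
                )
                used_lengths.add(plen)
                placed = True
                break
        if not placed:
            return None

    # final verification of every allele by the local splice oracle
    for al in alleles:
        plen = _splice_translate(seq, [(al.offset, al.ref, al.alt)])
        if plen != al.protein_len or plen > 0.9 * ref_len:
            return None
    if not alleles:
        return None
    gene = _SimGene(
        gene_id=gene_id,
        strand=strand,
        cds=seq,
        intervals=intervals,
        alleles=alleles,
        neutral=neutral,
        gene_class=gene_class,
        target_freq=target_freq,
    )
    return gene, end


def _cds_to_genomic(intervals, strand, offset):
    cum = 0
    ordered = intervals if strand == "+" else list(reversed(intervals))
    for s, e in ordered:
        ln = e - s + 1
        if offset < cum + ln:
            return s + (offset - cum) if strand == "+" else e - (offset - cum)
        cum += ln
    raise ValueError(f"CDS offset {offset} outside intervals")


def _genomic_record(gene: "_SimGene", offset: int, ref: str, alt: str):
    """Map a CDS-space edit to a VCF-style (pos, REF, ALT) genomic record."""
    if gene.strand == "+":
        pos = _cds_to_genomic(gene.intervals, "+", offset)
        return pos, ref, alt
    # minus strand: reverse-complement alleles; anchor at the lowest genomic
    # coordinate of the REF span
    end_off = offset + len(ref) - 1
    pos = _cds_to_genomic(gene.intervals, "-", end_off)
    rc = lambda s: s.translate(_COMPLEMENT)[::-1]
    return pos, rc(ref), rc(alt)


# ---------------------------------------------------------------------------
# Panel simulation


@dataclass
class SyntheticPanel:
    """Joint simulated inputs: raster, ecotypes, variants, phenotypes, truth."""

    config: SimulationConfig
    grid: VhiGrid
    ecotypes: pd.DataFrame
    background: np.ndarray
    genes: pd.DataFrame
    true_states: pd.DataFrame
    truth: GroundTruth
    sim_genes: list
    vcf_records: list  # (pos, gene_id, ref, alt, genotypes int8 array)
    alignments: dict  # gene_id -> (ingroup {name: seq}, outgroup seq)
    mk_planted: dict  # gene_id -> realized (pn, ps, dn, ds) planted counts

    def write(self, outdir, include_raster: bool = True) -> dict:
        """Emit VCF, GFF3, CDS FASTA, ecotype CSV, alignments, truth JSON.

        Identical config + seed produce byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "variants.vcf",
            "gff3": outdir / "genes.gff3",
            "fasta": outdir / "cds.fasta",
            "ecotypes": outdir / "ecotypes.csv",
            "truth": outdir / "truth.json",
            "alignments": outdir / "alignments",
        }
        self._write_vcf(paths["vcf"])
        self._write_gff3(paths["gff3"])
        self._write_fasta(paths["fasta"])
        cols = ["id", "lat", "lon", "flowering_days", "min_temp"]
        self.ecotypes[cols].to_csv(paths["ecotypes"], index=False, float_format="%.6f")
        self.truth.to_json(paths["truth"])
        paths["alignments"].mkdir(exist_ok=True)
        for gene_id, (ingroup, out) in sorted(self.alignments.items()):
            with open(paths["alignments"] / f"{gene_id}.fasta", "w") as fh:
                for name, seq in ingroup.items():
                    fh.write(f">{name}\n{seq}\n")
                fh.write(f">outgroup\n{out}\n")
        if include_raster:
            paths["raster"] = outdir / "raster.csv"
            self.grid.to_csv(paths["raster"])
        return paths

    def _write_vcf(self, path) -> None:
        samples = list(self.ecotypes["id"])
        chrom_len = max(g.intervals[-1][1] for g in self.sim_genes) + 1000
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID=chr1,length={chrom_len}>\n")
            fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for pos, gene_id, ref, alt, gts in sorted(
                self.vcf_records, key=lambda r: (r[0], r[2], r[3])
            ):
                gt_str = "\t".join(
                    "." if g < 0 else str(int(g)) for g in gts
                )
                fh.write(
                    f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tGENE={gene_id}\tGT\t{gt_str}\n"
                )

    def _write_gff3(self, path) -> None:
        cfg = self.config
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gene in self.sim_genes:
                s, e = gene.intervals[0][0], gene.intervals[-1][1]
                gid = gene.gene_id
                fh.write(
                    f"chr1\tsim\tgene\t{s}\t{e}\t.\t{gene.strand}\t.\tID={gid}\n"
                )
                fh.write(
                    f"chr1\tsim\tmRNA\t{s}\t{e}\t.\t{gene.strand}\t.\tID={gid}.1;Parent={gid}\n"
                )
                for i, (cs, ce) in enumerate(gene.intervals, 1):
                    fh.write(
                        f"chr1\tsim\tCDS\t{cs}\t{ce}\t.\t{gene.strand}\t0\t"
                        f"ID={gid}.1.cds{i};Parent={gid}.1\n"
                    )
            # multi-transcript decoys: dropped by the single-model filter
            cursor = max(g.intervals[-1][1] for g in self.sim_genes) + 2000
            for d in range(cfg.n_multi_transcript_decoys):
                gid = f"decoy{d:02d}"
                s, e = cursor, cursor + 299
                fh.write(f"chr1\tsim\tgene\t{s}\t{e}\t.\t+\t.\tID={gid}\n")
                for t in (1, 2):
                    fh.write(
                        f"chr1\tsim\tmRNA\t{s}\t{e}\t.\t+\t.\tID={gid}.{t};Parent={gid}\n"
                    )
                    fh.write(
                        f"chr1\tsim\tCDS\t{s}\t{e}\t.\t+\t0\tID={gid}.{t}.cds1;Parent={gid}.{t}\n"
                    )
                cursor = e + 500

    def _write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for gene in self.sim_genes:
                fh.write(f">{gene.gene_id}\n{gene.cds}\n")
            rng = np.random.default_rng([self.config.seed, 77])
            for d in range(self.config.n_multi_transcript_decoys):
                seq = "ATG" + "".join(_random_codon(rng) for _ in range(98)) + "TAA"
                fh.write(f">decoy{d:02d}\n{seq}\n")


def _solve_intercept(target, slope_term):
    """alpha with mean sigmoid(alpha + slope_term) == target, by bisection."""
    lo, hi = -12.0, 12.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if np.mean(1 / (1 + np.exp(-(mid + slope_term)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _plant_alignment(rng, gene, counts, n_ingroup, gap_rate):
    """Ingroup + outgroup codon alignment with planted PN/PS/DN/DS counts."""
    pn, ps, dn, ds = counts
    cds = gene.cds
    L = len(cds) // 3
    ingroup = {f"acc{i:02d}": list(cds) for i in range(n_ingroup)}
    out = list(cds)
    free = list(rng.permutation(np.arange(1, L - 1)))

    def aa_of(codon):
        return str(Seq(codon).translate())

    def plant(target_rows, synonymous):
        while free:
            c = int(free.pop())
            codon = cds[3 * c : 3 * c + 3]
            sites = list(rng.permutation([0, 1, 2]))
            for w in sites:
                for b in rng.permutation(list(_BASES)):
                    if b == codon[w]:
                        continue
                    alt = codon[:w] + b + codon[w + 1 :]
                    same = aa_of(alt) == aa_of(codon)
                    if aa_of(alt) == "*":
                        continue
                    if same == synonymous:
                        for rowset in target_rows:
                            rowset[3 * c + w] = b
                        return True
        return False

    row_names = list(ingroup)
    realized = [0, 0, 0, 0]
    for _ in range(pn):
        realized[0] += plant([ingroup[str(rng.choice(row_names[1:]))]], synonymous=False)
    for _ in range(ps):
        realized[1] += plant([ingroup[str(rng.choice(row_names[1:]))]], synonymous=True)
    for _ in range(dn):
        realized[2] += plant([out], synonymous=False)
    for _ in range(ds):
        realized[3] += plant([out], synonymous=True)
    if free and rng.random() < gap_rate:  # gap codon in the outgroup
        c = int(free.pop())
        out[3 * c : 3 * c + 3] = list("---")
    return {k: "".join(v) for k, v in ingroup.items()}, "".join(out), tuple(realized)


def simulate_panel(
    config: SimulationConfig, grid: VhiGrid
) -> tuple[SyntheticPanel, GroundTruth]:
    """Simulate the ecotype panel, genomes, phenotypes and alignments.

    LoF carrier status per gene follows logit(p) = alpha_g + beta_g * index
    + cluster offset, with beta_g > 0 for spring-late causal genes, < 0 for
    summer-early, 0 for null genes; flowering time is baseline +
    effect_per_lof_day * (LoF count over spring-late causal genes) -
    effect_per_lof_day * (count over summer-early) + cluster effect +
    Gaussian noise.
    """
    rng = np.random.default_rng([config.seed, 23])
    rows, cols = config.grid_shape
    land = np.argwhere(~grid.water_mask)
    if config.n_ecotypes > len(land):
        raise ConfigError(
            f"n_ecotypes={config.n_ecotypes} exceeds {len(land)} land pixels"
        )
    pick = land[rng.choice(len(land), size=config.n_ecotypes, replace=False)]
    ids = [f"eco{i:04d}" for i in range(config.n_ecotypes)]
    jitter = rng.uniform(-0.3, 0.3, size=(config.n_ecotypes, 2)) * config.cell
    lats = grid.lat0 - pick[:, 0] * grid.cell + jitter[:, 0]
    lons = grid.lon0 + pick[:, 1] * grid.cell + jitter[:, 1]

    probs = grid.true_seasonal_probs
    index = np.log(
        probs["spring"][pick[:, 0], pick[:, 1]] / probs["summer"][pick[:, 0], pick[:, 1]]
    )
    clusters = rng.integers(0, config.clusters, size=config.n_ecotypes)
    cluster_logit = rng.normal(0, config.cluster_logit_sd, size=config.clusters)
    cluster_days = rng.normal(0, config.cluster_days_sd, size=config.clusters)

    # cluster-structured background genotypes (Balding-Nichols style)
    F = config.fst
    p_anc = rng.uniform(0.1, 0.9, size=config.n_background_markers)
    p_pop = rng.beta(
        p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F,
        size=(config.clusters, config.n_background_markers),
    )
    background = (
        rng.random((config.n_ecotypes, config.n_background_markers))
        < p_pop[clusters]
    ).astype(np.int8)

    # gene classes
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    classes = ["null"] * config.n_genes
    order = rng.permutation(config.n_genes)
    for i in order[: config.n_causal_spring_late]:
        classes[i] = "spring_late"
    for i in order[
        config.n_causal_spring_late : config.n_causal_spring_late + config.n_causal_summer_early
    ]:
        classes[i] = "summer_early"
    null_idx = [i for i in order if classes[i] == "null"]
    lowfreq = set(null_idx[: config.n_lowfreq_genes])

    slopes, effects, targets = {}, {}, {}
    for i, (gid, cls) in enumerate(zip(gene_ids, classes)):
        if cls == "spring_late":
            slopes[gid] = config.env_logit_slope
            effects[gid] = config.effect_per_lof_day
        elif cls == "summer_early":
            slopes[gid] = -config.env_logit_slope
            effects[gid] = -config.effect_per_lof_day
        else:
            slopes[gid] = 0.0
            effects[gid] = 0.0
        targets[gid] = (
            config.lowfreq_target
            if i in lowfreq
            else float(rng.uniform(*config.lof_freq_range))
        )

    # carrier draws
    carrier = np.zeros((config.n_ecotypes, config.n_genes), dtype=np.int8)
    for j, gid in enumerate(gene_ids):
        term = slopes[gid] * index + cluster_logit[clusters]
        alpha = _solve_intercept(targets[gid], term)
        p = 1 / (1 + np.exp(-(alpha + term)))
        carrier[:, j] = rng.random(config.n_ecotypes) < p

    spring_idx = [j for j, c in enumerate(classes) if c == "spring_late"]
    summer_idx = [j for j, c in enumerate(classes) if c == "summer_early"]
    flowering = (
        config.baseline_days
        + config.effect_per_lof_day * carrier[:, spring_idx].sum(axis=1)
        - config.effect_per_lof_day * carrier[:, summer_idx].sum(axis=1)
        + cluster_days[clusters]
        + rng.normal(0, config.noise_sd_days, size=config.n_ecotypes)
    )
    min_temp = 25.0 - 0.7 * lats + rng.normal(0, 2.0, size=config.n_ecotypes)

    # molecular realization
    sim_genes, cursor = [], 1000
    for gid, cls in zip(gene_ids, classes):
        gene, cursor = _build_gene(rng, gid, cls, targets[gid], cursor, config)
        sim_genes.append(gene)

    vcf_records = []
    n = config.n_ecotypes
    true_states = pd.DataFrame(
        0.0, index=pd.Index(ids, name="ecotype"), columns=gene_ids
    )
    for j, gene in enumerate(sim_genes):
        carriers = np.nonzero(carrier[:, j])[0]
        n_alleles = len(gene.alleles)
        weights = (np.arange(1, n_alleles + 1, dtype=float)) ** (-config.allele_skew)
        weights /= weights.sum()
        assignment = rng.choice(n_alleles, size=len(carriers), p=weights)
        gene_missing = np.zeros(n, dtype=bool)
        for a, allele in enumerate(gene.alleles):
            gts = np.zeros(n, dtype=np.int8)
            gts[carriers[assignment == a]] = 1
            if config.missing_rate > 0:
                miss = rng.random(n) < config.missing_rate
                gts[miss] = -1
                gene_missing |= miss
            pos, ref, alt = _genomic_record(gene, allele.offset, allele.ref, allele.alt)
            vcf_records.append((pos, gene.gene_id, ref, alt, gts))
        if gene.neutral is not None:
            gts = (rng.random(n) < config.neutral_variant_freq).astype(np.int8)
            if config.missing_rate > 0:
                gts[rng.random(n) < config.missing_rate] = -1
            pos, ref, alt = _genomic_record(gene, *gene.neutral)
            vcf_records.append((pos, gene.gene_id, ref, alt, gts))
        states = carrier[:, j].astype(float)
        states[gene_missing] = np.nan
        true_states[gene.gene_id] = states

    # ortholog alignments with planted MK counts
    alignments, mk_planted = {}, {}
    for gene in sim_genes:
        causal = gene.gene_class != "null"
        counts = (
            int(rng.poisson(config.mk_pn_assoc if causal else config.mk_pn_null)),
            int(rng.poisson(config.mk_ps)),
            int(rng.poisson(config.mk_dn_assoc if causal else config.mk_dn_null)),
            int(rng.poisson(config.mk_ds)),
        )
        ingroup, out, realized = _plant_alignment(
            rng, gene, counts, config.n_ingroup_aln, config.gap_codon_rate
        )
        alignments[gene.gene_id] = (ingroup, out)
        mk_planted[gene.gene_id] = realized

    ecotypes = pd.DataFrame(
        {
            "id": ids,
            "lat": lats,
            "lon": lons,
            "flowering_days": flowering,
            "min_temp": min_temp,
            "cluster": clusters,
            "row": pick[:, 0],
            "col": pick[:, 1],
            "drought_index_true": index,
        }
    )
    genes_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": classes,
            "target_freq": [targets[g] for g in gene_ids],
            "realized_freq": carrier.mean(axis=0),
            "strand": [g.strand for g in sim_genes],
            "n_exons": [len(g.intervals) for g in sim_genes],
            "n_alleles": [len(g.alleles) for g in sim_genes],
            "ref_protein_len": [len(g.cds) // 3 - 1 for g in sim_genes],
        }
    ).set_index("gene_id")
    truth = GroundTruth(
        gene_class=dict(zip(gene_ids, classes)),
        effect_days=effects,
        env_slope=slopes,
        cluster_labels=pd.Series(clusters, index=ids),
    )
    panel = SyntheticPanel(
        config=config,
        grid=grid,
        ecotypes=ecotypes,
        background=background,
        genes=genes_df,
        true_states=true_states,
        truth=truth,
        sim_genes=sim_genes,
        vcf_records=vcf_records,
        alignments=alignments,
        mk_planted=mk_planted,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Knockout experiment


def simulate_knockout_experiment(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Shelf-stratified randomized knockout experiment table.

    One knockout line per sampled candidate gene; most lines get a positive
    true flowering delay (uniform on ``knockout_effect_range`` days), a
    configurable few get ``knockout_negative_effect``.  Each plant's
    days-to-flower = wild-type mean + line effect + shelf effect + tray
    effect + residual.  Line effects are recorded into
    ``truth.line_effects``.
    """
    rng = np.random.default_rng([config.seed, 31])
    candidates = [g for g, c in truth.gene_class.items() if c == "spring_late"]
    pool = candidates + [g for g, c in truth.gene_class.items() if c == "summer_early"]
    pool += [g for g, c in truth.gene_class.items() if c == "null"]
    line_genes = pool[: config.knockout_lines]
    if len(line_genes) < config.knockout_lines:
        raise ConfigError("not enough genes to assign knockout lines")
    effects = rng.uniform(*config.knockout_effect_range, size=config.knockout_lines)
    neg = rng.choice(
        config.knockout_lines, size=config.n_negative_knockout_lines, replace=False
    )
    effects[neg] = config.knockout_negative_effect
    lines = [f"ko_{g}" for g in line_genes]
    truth.line_effects = {ln: float(e) for ln, e in zip(lines, effects)}
    truth.line_effects[config.wild_type] = 0.0

    shelf_eff = rng.normal(0, config.shelf_sd_days, size=config.n_shelves)
    tray_eff = rng.normal(
        0, config.tray_sd_days, size=(config.n_shelves, config.trays_per_shelf)
    )
    rows = []
    plant_list = []
    for line, eff in zip(lines, effects):
        plant_list += [(line, eff)] * config.reps_per_line
    plant_list += [(config.wild_type, 0.0)] * config.wt_reps
    # stratify: spread each line's reps across shelves as evenly as possible
    by_line: dict[str, list] = {}
    for line, eff in plant_list:
        by_line.setdefault(line, []).append(eff)
    for line, effs in by_line.items():
        shelf_order = list(rng.permutation(config.n_shelves))
        for r, eff in enumerate(effs):
            shelf = shelf_order[r % config.n_shelves]
            tray = int(rng.integers(config.trays_per_shelf))
            days = (
                config.baseline_days
                + eff
                + shelf_eff[shelf]
                + tray_eff[shelf, tray]
                + rng.normal(0, config.experiment_noise_sd)
            )
            rows.append((line, f"S{shelf}", f"T{tray}", days))
    table = pd.DataFrame(rows, columns=["line", "shelf", "tray", "days"])
    return table.sample(frac=1.0, random_state=config.seed).reset_index(drop=True)
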