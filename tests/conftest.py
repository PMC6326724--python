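"""Shared fixtures: synthetic panels at two scales and hand-built gene fixtures."""

import numpy as np
import pandas as pd
import pytest

import lofscan as L


@pytest.fixture(scope="session")
def small_cfg():
    return L.SimulationConfig(
        seed=11,
        n_ecotypes=300,
        n_genes=60,
        n_causal_spring_late=10,
        n_causal_summer_early=4,
        n_lowfreq_genes=4,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    grid = L.simulate_vhi_grid(small_cfg)
    panel, truth = L.simulate_panel(small_cfg, grid)
    return panel


@pytest.fixture(scope="session")
def small_paths(small_panel, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("panel")
    return small_panel.write(outdir, include_raster=False)


@pytest.fixture(scope="session")
def small_matrix(small_paths):
    return L.call_lof(
        small_paths["vcf"], small_paths["gff3"], small_paths["fasta"]
    )


@pytest.fixture(scope="session")
def small_predictors(small_panel, small_matrix):
    """Per-ecotype predictors computed through the climatology pipeline."""
    grid = small_panel.grid
    profile = L.seasonal_frequency(grid)
    index = L.drought_timing_index(profile)
    vals, _ = L.extract_at_locations(index, small_panel.ecotypes, profile)
    eco = small_panel.ecotypes.set_index("id")
    idx = small_matrix.states.index
    return pd.DataFrame(
        {
            "drought_timing": vals.reindex(idx),
            "flowering": eco["flowering_days"].reindex(idx),
            "latitude": eco["lat"].reindex(idx),
            "min_temp": eco["min_temp"].reindex(idx),
        }
    )


@pytest.fixture(scope="session")
def small_pcs(small_panel):
    K = L.kinship(small_panel.background)
    return L.structure_pcs(K, 3)


@pytest.fixture(scope="session")
def full_panel(tmp_path_factory):
    """Default-scale study system (500 ecotypes x 200 genes) with its
    called matrix, pipeline-derived predictors and structure PCs."""
    cfg = L.SimulationConfig(seed=101)
    grid = L.simulate_vhi_grid(cfg)
    panel, truth = L.simulate_panel(cfg, grid)
    paths = panel.write(tmp_path_factory.mktemp("full"), include_raster=False)
    matrix = L.call_lof(paths["vcf"], paths["gff3"], paths["fasta"])
    profile = L.seasonal_frequency(grid)
    index = L.drought_timing_index(profile)
    vals, _ = L.extract_at_locations(index, panel.ecotypes, profile)
    eco = panel.ecotypes.set_index("id")
    predictors = pd.DataFrame(
        {
            "drought_timing": vals,
            "flowering": eco["flowering_days"],
            "latitude": eco["lat"],
            "min_temp": eco["min_temp"],
        }
    ).reindex(matrix.states.index)
    pcs = L.structure_pcs(L.kinship(panel.background), 3)
    return {"panel": panel, "truth": truth, "matrix": matrix,
            "predictors": predictors, "pcs": pcs}


def write_gene_fixture(tmp_path, genes, vcf_rows=None, samples=("e1", "e2")):
    """Write GFF3 + CDS FASTA (+ optional VCF) for hand-built gene models.

    ``genes``: list of dicts with gene_id, strand, intervals [(s, e), ...]
    (genomic ascending), cds (transcript orientation), n_mrna (default 1).
    ``vcf_rows``: list of (pos, ref, alt, gt_string_per_sample list).
    """
    gff = tmp_path / "genes.gff3"
    fasta = tmp_path / "cds.fasta"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g["intervals"][0][0], g["intervals"][-1][1]
            gid, strand = g["gene_id"], g["strand"]
            fh.write(f"chr1\ttest\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}\n")
            for t in range(1, g.get("n_mrna", 1) + 1):
                fh.write(
                    f"chr1\ttest\tmRNA\t{s}\t{e}\t.\t{strand}\t.\tID={gid}.{t};Parent={gid}\n"
                )
                for i, (cs, ce) in enumerate(g["intervals"], 1):
                    fh.write(
                        f"chr1\ttest\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t"
                        f"ID={gid}.{t}.c{i};Parent={gid}.{t}\n"
                    )
    with open(fasta, "w") as fh:
        for g in genes:
            fh.write(f">{g['gene_id']}\n{g['cds']}\n")
    paths = {"gff3": gff, "fasta": fasta}
    if vcf_rows is not None:
        vcf = tmp_path / "variants.vcf"
        with open(vcf, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n##contig=<ID=chr1,length=100000>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            for pos, ref, alt, gts in sorted(vcf_rows):
                fh.write(
                    f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )
        paths["vcf"] = vcf
    return paths
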