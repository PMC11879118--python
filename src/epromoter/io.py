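"""On-disk text formats for the synthetic world and pipeline inputs.

Annotation is written as a minimal GTF (1-based, inclusive) with transcript
features; fragments and feature tracks as BED; the haplotype panel as a
valid phased VCF 4.2 (haplotypes paired into diploid samples, read back
with pysam); everything else as TSV. All in-memory coordinates stay 0-based
half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .starr import FragmentSet
from .synthetic import PlantedTruth, SyntheticConfig, SyntheticWorld

_TX_SPAN = 300  # nominal transcript span written to the GTF


def write_gtf(annotation: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for rec in annotation.itertuples():
            tss = int(rec.tss)
            if rec.strand == "+":
                start1, end1 = tss + 1, tss + _TX_SPAN
            else:
                start1, end1 = max(tss + 2 - _TX_SPAN, 1), tss + 1
            attrs = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}"; '
                f'gene_biotype "protein_coding";'
            )
            fh.write(
                f"{rec.chrom}\tsynthetic\ttranscript\t{start1}\t{end1}\t.\t"
                f"{rec.strand}\t.\t{attrs}\n"
            )


def read_gtf(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "transcript":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            strand = f[6]
            tss = int(f[3]) - 1 if strand == "+" else int(f[4]) - 1
            rows.append(
                {
                    "gene_id": attrs["gene_id"].strip('"'),
                    "transcript_id": attrs["transcript_id"].strip('"'),
                    "chrom": f[0],
                    "strand": strand,
                    "tss": tss,
                }
            )
    return pd.DataFrame(rows)


def write_bed(df: pd.DataFrame, path: Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: Path, extra: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra or [])
    return pd.read_csv(path, sep="\t", header=None, names=names)


def write_vcf(world: SyntheticWorld, path: Path) -> None:
    n_hap = world.panel.shape[0]
    if n_hap % 2:
        raise ValueError("haplotype count must be even to pair into diploid samples")
    samples = [f"S{i + 1:04d}" for i in range(n_hap // 2)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, size in world.config.chrom_sizes().items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for rec in world.variants.itertuples():
            col = world.panel[:, int(rec.col)]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_hap // 2)
            )
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\tC\tT\t.\tPASS\t"
                f"MAF={rec.maf:.6f}\tGT\t{gts}\n"
            )


def read_vcf(path: Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Variant table (1-based pos, panel column index, MAF) plus the
    haplotype matrix, phased GTs split back into haplotype columns."""
    vf = pysam.VariantFile(str(path))
    rows, columns = [], []
    for j, rec in enumerate(vf):
        hap = []
        for sample in rec.samples.values():
            hap.extend(sample["GT"])
        columns.append(np.asarray(hap, dtype=np.int8))
        maf = float(rec.info.get("MAF", np.minimum(np.mean(hap), 1 - np.mean(hap))))
        rows.append(
            {"snp_id": rec.id, "chrom": rec.chrom, "pos": rec.pos, "col": j,
             "maf": maf, "is_common": maf >= 0.01}
        )
    panel = np.stack(columns, axis=1) if columns else np.zeros((0, 0), dtype=np.int8)
    return pd.DataFrame(rows), panel


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Serialize every input of the world as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(world.config.__dict__, fh, indent=1, sort_keys=True)
    write_gtf(world.annotation, out / "annotation.gtf")
    for (lib, rep), fs in sorted(world.fragment_sets.items()):
        write_bed(fs.fragments, out / f"fragments_{lib}_rep{rep}.bed", extra=["strand"])
    world.expression.to_csv(out / "expression.tsv", sep="\t")
    write_vcf(world, out / "panel.vcf")
    world.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    world.gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
    world.eqtls.to_csv(out / "eqtl.tsv", sep="\t", index=False)
    world.pp_interactions.to_csv(out / "pp.bedpe", sep="\t", index=False, header=False)
    zdf = pd.DataFrame(world.crispri_z, index=world.crispri_genes,
                       columns=world.crispri_genes)
    zdf.round(4).to_csv(out / "crispri_z.tsv", sep="\t")
    world.mpra_snps.to_csv(out / "mpra.tsv", sep="\t", index=False)
    world.tfskew_snps.to_csv(out / "tfskew.tsv", sep="\t", index=False)
    tracks = out / "tracks"
    tracks.mkdir(exist_ok=True)
    for kind, df in world.tracks.items():
        df.to_csv(tracks / f"{kind}.tsv", sep="\t", index=False)
    for cond, df in world.allelic_fragments.items():
        df.to_csv(out / f"allelic_{cond}.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        fh.write(world.truth.to_json())


def load_world(indir: str | Path) -> SyntheticWorld:
    """Load a serialized world; the round-trip inverse of :func:`write_world`."""
    from .intervals import GenomicInterval

    ind = Path(indir)
    with open(ind / "config.json") as fh:
        config = SyntheticConfig(**json.load(fh))
    annotation = read_gtf(ind / "annotation.gtf")
    fragment_sets = {}
    for path in sorted(ind.glob("fragments_*_rep*.bed")):
        stem = path.stem  # fragments_<lib>_rep<k>
        _, lib, rep_tag = stem.split("_")
        rep = int(rep_tag.replace("rep", ""))
        df = read_bed(path, extra=["strand"])
        fragment_sets[(lib, rep)] = FragmentSet(
            library_label=lib, replicate=rep, fragments=df
        )
    expression = pd.read_csv(ind / "expression.tsv", sep="\t", index_col=0)
    var_vcf, panel = read_vcf(ind / "panel.vcf")
    variants = pd.read_csv(ind / "variants.tsv", sep="\t", keep_default_na=False)
    gwas = pd.read_csv(ind / "gwas.tsv", sep="\t")
    eqtls = pd.read_csv(ind / "eqtl.tsv", sep="\t")
    pp = pd.read_csv(
        ind / "pp.bedpe", sep="\t", header=None,
        names=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "source"],
    )
    zdf = pd.read_csv(ind / "crispri_z.tsv", sep="\t", index_col=0)
    mpra = pd.read_csv(ind / "mpra.tsv", sep="\t")
    tfskew = pd.read_csv(ind / "tfskew.tsv", sep="\t")
    tracks = {
        p.stem: pd.read_csv(p, sep="\t") for p in sorted((ind / "tracks").glob("*.tsv"))
    }
    allelic = {
        p.stem.replace("allelic_", ""): pd.read_csv(p, sep="\t")
        for p in sorted(ind.glob("allelic_*.tsv"))
    }
    with open(ind / "truth.json") as fh:
        truth = PlantedTruth.from_json(fh.read())
    from .epcall import define_promoters

    promoters = define_promoters(
        annotation, window=config.promoter_window, chrom_sizes=config.chrom_sizes()
    )
    canonical = promoters[promoters["transcript_id"].str.endswith("T1")]
    captured = sorted(
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in canonical.itertuples()
    )
    return SyntheticWorld(
        config=config,
        annotation=annotation,
        captured_regions=captured,
        fragment_sets=fragment_sets,
        expression=expression,
        variants=variants,
        panel=panel,
        gwas=gwas,
        eqtls=eqtls,
        pp_interactions=pp,
        crispri_genes=list(zdf.index),
        crispri_z=zdf.to_numpy(dtype=float),
        mpra_snps=mpra,
        tfskew_snps=tfskew,
        tracks=tracks,
        allelic_fragments=allelic,
        truth=truth,
    )
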