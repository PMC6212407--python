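"""Synthetic TSS-seq data with known ground truth.

The generator builds a small genome annotation (protein-coding genes with
exon/intron/UTR structure plus rRNA/tRNA/snRNA/snoRNA decoys), plants TSS
clusters of known category, expression and fold change, and emits per-sample
aligned 5' tags with the nuisance structure the pipeline must remove: PCR
duplicates sharing a UMI, contaminant tags inside structural-RNA genes, and
a fraction of low-MAPQ multimappers.  Tag 5' positions scatter around the
planted summit with a discretized Gaussian; real TSS shape families
(sharp/broad) are approximated by the spread parameter only.

Tags are emitted directly as AlignedTag records so no genome aligner is
needed; an optional FASTQ emission (UMI prepended, adapter appended)
exercises the read-level preprocessing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import Annotator
from .core import AlignedTag, GenomeAnnotation, GeneModel, Read
from .preprocess import DEFAULT_ADAPTER
from .tags import DEFAULT_EXCLUDED_BIOTYPES, write_tags_tsv
from . import io

DEFAULT_BIOTYPE_MIX = {
    "protein_coding": 0.85,
    "rRNA": 0.05,
    "tRNA": 0.05,
    "snRNA": 0.025,
    "snoRNA": 0.025,
}
#: Category proportions loosely shaped like a promoter-dominated TSS landscape.
DEFAULT_CATEGORY_MIX = {
    "promoter": 0.45,
    "proximal": 0.10,
    "utr5": 0.10,
    "exon": 0.10,
    "intron": 0.05,
    "antisense": 0.10,
    "intergenic": 0.10,
}
#: Fractions of clusters that are null / up- / down-regulated in the cold
#: condition, with their fold changes.
DEFAULT_EFFECT_SPEC = {"null": (0.80, 1.0), "up": (0.10, 4.0), "down": (0.10, 0.25)}
CONDITIONS = ("control", "cold")


def _exact_allocation(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation of n items to the mix fractions."""
    total = sum(mix.values())
    raw = {k: v / total * n for k, v in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:rest]:
        counts[k] += 1
    return counts


def make_genome(
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 40,
    biotype_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> GenomeAnnotation:
    """Generate a deterministic annotation with non-overlapping genes."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    ann = GenomeAnnotation(chrom_sizes=chrom_sizes)
    if n_genes == 0:
        return ann
    mix = dict(biotype_mix or DEFAULT_BIOTYPE_MIX)
    counts = _exact_allocation(mix, n_genes)
    biotypes = [b for b, c in counts.items() for _ in range(c)]
    rng.shuffle(biotypes)

    chrom_names = sorted(chrom_sizes)
    ci = 0
    cursor = 600  # leave room for upstream windows of the first gene
    for gi, biotype in enumerate(biotypes):
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "protein_coding":
            n_ex = int(rng.integers(1, 5))
            exon_lens = rng.integers(250, 700, size=n_ex)
            intron_lens = rng.integers(120, 400, size=max(n_ex - 1, 0))
        else:
            n_ex = 1
            exon_lens = rng.integers(100, 300, size=1)
            intron_lens = np.array([], dtype=int)
        gene_len = int(exon_lens.sum() + intron_lens.sum())
        gap = int(rng.integers(1300, 2400))
        while ci < len(chrom_names) and cursor + gene_len + 600 > chrom_len:
            ci += 1
            cursor = 600
        if ci >= len(chrom_names):
            raise ValueError(
                f"cannot place {n_genes} genes in {n_chrom} x {chrom_len} bp "
                f"at the requested density"
            )
        chrom = chrom_names[ci]
        start = cursor
        exons = []
        p = start
        for k in range(n_ex):
            exons.append((p, p + int(exon_lens[k])))
            p += int(exon_lens[k])
            if k < n_ex - 1:
                p += int(intron_lens[k])
        end = start + gene_len
        gene = GeneModel(
            gene_id=f"G{gi + 1:03d}",
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            biotype=biotype,
            exons=exons,
        )
        if biotype == "protein_coding":
            u5 = min(150, exons[0][1] - exons[0][0] - 50)
            u3 = min(150, exons[-1][1] - exons[-1][0] - 50)
            if strand == "+":
                gene.utr5 = [(exons[0][0], exons[0][0] + u5)]
                gene.utr3 = [(exons[-1][1] - u3, exons[-1][1])]
            else:
                gene.utr5 = [(exons[-1][1] - u5, exons[-1][1])]
                gene.utr3 = [(exons[0][0], exons[0][0] + u3)]
        ann.genes.append(gene)
        cursor = end + gap
    ann.validate()
    return ann


@dataclass
class TruthTable:
    """Planted clusters plus the nuisance rates used to generate tags."""

    clusters: pd.DataFrame
    seed: int
    dup_rate: float = 0.0
    contam_frac: float = 0.0
    lowmapq_frac: float = 0.0

    def __post_init__(self) -> None:
        if len(self.clusters) and (self.clusters["mean_expr"] <= 0).any():
            raise ValueError("planted mean expression must be positive")
        for r in (self.dup_rate, self.contam_frac, self.lowmapq_frac):
            if not 0 <= r <= 1:
                raise ValueError("rates must be fractions in [0, 1]")


def plant_tss(
    annotation: GenomeAnnotation,
    n_clusters: int = 200,
    category_mix: dict[str, float] | None = None,
    effect_spec: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    min_separation: int = 60,
    max_tries: int = 500,
) -> TruthTable:
    """Plant TSS cluster summits whose category is verified by the annotator.

    Each summit is rejection-sampled until the pipeline's own annotator
    assigns the requested category, summits on the same strand are at least
    ``min_separation`` bp apart, and no summit falls within 25 bp of an
    excluded-biotype gene (whose tags the pipeline would filter out).
    """
    rng = np.random.default_rng(seed)
    annotator = Annotator(annotation)
    cat_counts = _exact_allocation(dict(category_mix or DEFAULT_CATEGORY_MIX), n_clusters)
    effects = dict(effect_spec or DEFAULT_EFFECT_SPEC)
    eff_counts = _exact_allocation({k: v[0] for k, v in effects.items()}, n_clusters)
    eff_labels = [k for k, c in eff_counts.items() for _ in range(c)]
    rng.shuffle(eff_labels)

    coding = [g for g in annotation.genes if g.biotype == "protein_coding"]
    decoys = annotation.genes_by_biotype(DEFAULT_EXCLUDED_BIOTYPES)
    planted: dict[tuple[str, str], list[int]] = {}

    def far_enough(chrom: str, strand: str, pos: int) -> bool:
        if any(abs(pos - q) < min_separation for q in planted.get((chrom, strand), [])):
            return False
        return not any(
            g.chrom == chrom and g.start - 25 <= pos < g.end + 25 for g in decoys
        )

    def candidate(cat: str) -> tuple[str, str, int] | None:
        if cat in ("promoter", "proximal", "utr5", "exon", "intron", "antisense"):
            if not coding:
                return None
            g = coding[rng.integers(len(coding))]
            sign = 1 if g.strand == "+" else -1
            if cat == "promoter":
                r = int(rng.integers(-100, 101))
                return g.chrom, g.strand, g.tss + sign * r
            if cat == "proximal":
                r = int(rng.integers(-500, -100))
                return g.chrom, g.strand, g.tss + sign * r
            if cat == "utr5":
                if not g.utr5:
                    return None
                a, b = g.utr5[rng.integers(len(g.utr5))]
                return g.chrom, g.strand, int(rng.integers(a, b))
            if cat == "exon":
                a, b = g.exons[rng.integers(len(g.exons))]
                return g.chrom, g.strand, int(rng.integers(a, b))
            if cat == "intron":
                return g.chrom, g.strand, int(rng.integers(g.start, g.end))
            if cat == "antisense":
                other = "-" if g.strand == "+" else "+"
                return g.chrom, other, int(rng.integers(g.start, g.end))
        chroms = sorted(annotation.chrom_sizes)
        chrom = chroms[rng.integers(len(chroms))]
        strand = "+" if rng.random() < 0.5 else "-"
        return chrom, strand, int(rng.integers(600, annotation.chrom_sizes[chrom] - 600))

    rows = []
    idx = 0
    for cat in sorted(cat_counts):
        for _ in range(cat_counts[cat]):
            placed = False
            for _try in range(max_tries):
                c = candidate(cat)
                if c is None:
                    break
                chrom, strand, pos = c
                if pos < 0 or pos >= annotation.chrom_sizes[chrom]:
                    continue
                if not far_enough(chrom, strand, pos):
                    continue
                if annotator.category_at(chrom, strand, pos) != cat:
                    continue
                planted.setdefault((chrom, strand), []).append(pos)
                effect = eff_labels[idx]
                rows.append(
                    {
                        "cluster": f"T{idx + 1:04d}",
                        "chrom": chrom,
                        "strand": strand,
                        "summit": pos,
                        "spread_sd": float(rng.choice([1.0, 2.0, 4.0], p=[0.5, 0.3, 0.2])),
                        "category": cat,
                        "mean_expr": float(rng.lognormal(np.log(40.0), 0.8)),
                        "fc": effects[effect][1],
                        "effect": effect,
                    }
                )
                idx += 1
                placed = True
                break
            if not placed:
                raise ValueError(f"category {cat!r} unrealizable in this annotation")
    df = pd.DataFrame(rows).sort_values(["chrom", "strand", "summit"]).reset_index(drop=True)
    return TruthTable(clusters=df, seed=seed)


_BASES = np.array(list("ACGT"))


def _random_umis(rng: np.random.Generator, n: int, k: int = 8) -> list[str]:
    """Distinct random k-mers: biological molecules carry distinct UMIs, so a
    shared (position, UMI) pair marks a PCR copy, never a coincidence."""
    if n == 0:
        return []
    codes = rng.choice(4**k, size=n, replace=False)
    out = []
    for c in codes:
        word = []
        for _ in range(k):
            word.append("ACGT"[c & 3])
            c >>= 2
        out.append("".join(word))
    return out


def simulate_tags(
    truth: TruthTable,
    annotation: GenomeAnnotation,
    samples_per_condition: int = 2,
    library_scale: float = 1.0,
    dispersion: float = 0.05,
    dup_rate: float = 0.3,
    contam_frac: float = 0.1,
    lowmapq_frac: float = 0.05,
    tag_len: int = 50,
    seed: int = 0,
    size_factors: dict[str, float] | None = None,
) -> tuple[dict[str, list[AlignedTag]], dict[str, str]]:
    """Emit per-sample aligned 5' tags for a two-condition design.

    Per cluster and sample the tag count is negative-binomial with mean
    ``mean_expr * fc^[cold] * size_factor * library_scale``; tag positions
    scatter around the summit; every tag carries a random 8-mer UMI.  PCR
    duplicates (same position and UMI, new read id) are re-emitted with
    probability ``dup_rate``; contaminants are placed uniformly inside
    excluded-biotype genes; ``lowmapq_frac`` of tags get MAPQ < 10, the rest
    MAPQ 255.

    Returns ``(tags_by_sample, condition_by_sample)``.
    """
    if library_scale <= 0:
        raise ValueError("library_scale must be positive")
    truth_rates = TruthTable(  # validates the nuisance rates
        clusters=truth.clusters, seed=truth.seed, dup_rate=dup_rate,
        contam_frac=contam_frac, lowmapq_frac=lowmapq_frac,
    )
    del truth_rates
    rng = np.random.default_rng(seed)
    samples = [
        (f"{cond}_{i + 1}", cond)
        for cond in CONDITIONS
        for i in range(samples_per_condition)
    ]
    if size_factors is None:
        size_factors = {s: float(rng.uniform(0.85, 1.2)) for s, _ in samples}
    decoys = annotation.genes_by_biotype(DEFAULT_EXCLUDED_BIOTYPES)

    tags_by_sample: dict[str, list[AlignedTag]] = {}
    condition_by_sample = dict(samples)
    for sample, cond in samples:
        sf = size_factors[sample]
        tags: list[AlignedTag] = []
        serial = 0

        def emit(chrom: str, strand: str, pos: int, umi: str) -> None:
            nonlocal serial
            serial += 1
            size = annotation.chrom_sizes[chrom]
            pos = int(min(max(pos, 0), size - 1))
            if strand == "+":
                block = (pos, min(pos + tag_len, size))
            else:
                block = (max(pos - tag_len + 1, 0), pos + 1)
            mapq = int(rng.integers(0, 10)) if rng.random() < lowmapq_frac else 255
            tags.append(
                AlignedTag(
                    chrom=chrom, strand=strand, pos5=pos, mapq=mapq, umi=umi,
                    sample=sample, read_id=f"{sample}.r{serial:07d}", blocks=(block,),
                )
            )

        for row in truth.clusters.itertuples():
            mean = row.mean_expr * library_scale * sf
            if cond == "cold":
                mean *= row.fc
            if dispersion > 1e-12:
                n_nb = 1.0 / dispersion
                count = int(rng.negative_binomial(n_nb, n_nb / (n_nb + mean)))
            else:
                count = int(rng.poisson(mean))
            if count == 0:
                continue
            offsets = np.rint(rng.normal(0.0, row.spread_sd, size=count)).astype(int)
            for off, umi in zip(offsets, _random_umis(rng, count)):
                emit(row.chrom, row.strand, row.summit + off, umi)

        n_signal = len(tags)
        if decoys and contam_frac > 0:
            n_contam = int(rng.binomial(n_signal, contam_frac))
            for umi in _random_umis(rng, n_contam):
                g = decoys[rng.integers(len(decoys))]
                strand = "+" if rng.random() < 0.5 else "-"
                emit(g.chrom, strand, int(rng.integers(g.start, g.end)), umi)

        if dup_rate > 0:
            dup_flags = rng.random(len(tags)) < dup_rate
            for t, is_dup in zip(list(tags), dup_flags):
                if is_dup:
                    tags.append(
                        AlignedTag(
                            chrom=t.chrom, strand=t.strand, pos5=t.pos5, mapq=t.mapq,
                            umi=t.umi, sample=t.sample, read_id=t.read_id + ".dup",
                            blocks=t.blocks,
                        )
                    )
        tags_by_sample[sample] = tags
    return tags_by_sample, condition_by_sample


def fastq_from_tags(
    tags: list[AlignedTag],
    path: str,
    body_len: int = 30,
    adapter: str = DEFAULT_ADAPTER,
    adapter_frac: float = 0.5,
    seed: int = 0,
) -> dict[str, int]:
    """Write tags as raw FASTQ reads: 5' UMI + random body (+ 3' adapter).

    The genome is not sequence-realistic, so read bodies are random DNA;
    the point is to exercise adapter trimming and UMI extraction with known
    ground truth.  Returns counts including how many reads carry the
    adapter.
    """
    rng = np.random.default_rng(seed)
    n_adapter = 0

    def reads():
        nonlocal n_adapter
        for t in tags:
            # the last 13 bases avoid A/C so no chance suffix can look like a
            # partial adapter; only the deliberately appended adapter trims
            head = "".join(_BASES[rng.integers(0, 4, size=max(body_len - 13, 0))])
            tail = "".join(np.array(["G", "T"])[rng.integers(0, 2, size=min(body_len, 13))])
            bases = t.umi + head + tail
            if rng.random() < adapter_frac:
                bases += adapter
                n_adapter += 1
            yield Read(id=t.read_id, bases=bases, quals="I" * len(bases))

    n = io.write_fastq(reads(), path)
    return {"reads": n, "with_adapter": n_adapter}


def evaluate_recovery(
    truth: TruthTable,
    clusters,
    min_mean: float = 20.0,
    summit_tol: int = 5,
) -> tuple[float, pd.DataFrame]:
    """Fraction of well-expressed planted clusters recovered by the pipeline.

    A planted cluster counts as expressed if its across-condition mean
    (mean_expr * (1 + fc) / 2) is at least ``min_mean``, and as recovered if
    a called cluster on the same chromosome and strand has its summit within
    ``summit_tol`` bp of the planted summit.
    """
    called: dict[tuple[str, str], list[int]] = {}
    for c in clusters:
        called.setdefault((c.chrom, c.strand), []).append(c.summit)
    rows = []
    for row in truth.clusters.itertuples():
        mean_across = row.mean_expr * (1.0 + row.fc) / 2.0
        summits = called.get((row.chrom, row.strand), [])
        hit = any(abs(s - row.summit) <= summit_tol for s in summits)
        rows.append(
            {
                "cluster": row.cluster,
                "mean_across": mean_across,
                "expressed": mean_across >= min_mean,
                "recovered": hit,
            }
        )
    df = pd.DataFrame(rows)
    expressed = df[df["expressed"]]
    frac = float(expressed["recovered"].mean()) if len(expressed) else float("nan")
    return frac, df


@dataclass
class SimulatedDataset:
    annotation: GenomeAnnotation
    truth: TruthTable
    tags_by_sample: dict[str, list[AlignedTag]]
    condition_by_sample: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)


def generate_dataset(
    outdir: str | Path | None = None,
    seed: int = 0,
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 40,
    n_clusters: int = 200,
    samples_per_condition: int = 2,
    dup_rate: float = 0.3,
    contam_frac: float = 0.1,
    lowmapq_frac: float = 0.05,
    dispersion: float = 0.05,
    **plant_kwargs,
) -> SimulatedDataset:
    """Small preset: genome + truth + per-sample tag tables, optionally on disk.

    Seeds for the three stages are derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_truth, s_tags = (int(s % (2**31)) for s in ss.generate_state(3))
    ann = make_genome(
        n_chrom=n_chrom, chrom_len=chrom_len, n_genes=n_genes, seed=s_genome
    )
    truth = plant_tss(ann, n_clusters=n_clusters, seed=s_truth, **plant_kwargs)
    tags_by_sample, condition_by_sample = simulate_tags(
        truth,
        ann,
        samples_per_condition=samples_per_condition,
        dup_rate=dup_rate,
        contam_frac=contam_frac,
        lowmapq_frac=lowmapq_frac,
        dispersion=dispersion,
        seed=s_tags,
    )
    truth.dup_rate = dup_rate
    truth.contam_frac = contam_frac
    truth.lowmapq_frac = lowmapq_frac

    ds = SimulatedDataset(ann, truth, tags_by_sample, condition_by_sample)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gff = outdir / "annotation.gff3"
        io.write_gff(ann, gff)
        ds.paths["gff"] = gff
        truth_path = outdir / "truth.tsv"
        truth.clusters.to_csv(truth_path, sep="\t", index=False)
        ds.paths["truth"] = truth_path
        sheet_rows = []
        for sample, tags in tags_by_sample.items():
            p = outdir / f"tags_{sample}.tsv"
            write_tags_tsv(tags, p)
            ds.paths[f"tags_{sample}"] = p
            sheet_rows.append(
                {"sample": sample, "condition": condition_by_sample[sample], "tags": str(p)}
            )
        sheet = outdir / "samples.tsv"
        pd.DataFrame(sheet_rows).to_csv(sheet, sep="\t", index=False)
        ds.paths["samples"] = sheet
    return ds
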