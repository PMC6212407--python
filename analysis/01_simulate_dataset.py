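"""Generate the small synthetic TSS-seq study: 2 conditions x 2 replicates,
200 planted TSS clusters, 30% PCR duplication, 10% structural-RNA
contamination, 5% low-MAPQ multimappers.

Writes results/sim/: annotation.gff3, truth.tsv, per-sample tag tables and
the sample sheet consumed by 02_run_pipeline.py.
"""
from pathlib import Path

from captss.simulate import generate_dataset

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    ds = generate_dataset(outdir=OUT, seed=SEED)
    truth = ds.truth.clusters
    print(f"wrote {OUT}")
    print(f"genes: {len(ds.annotation.genes)} over {len(ds.annotation.chrom_sizes)} chromosomes")
    print(f"planted clusters: {len(truth)}")
    print("category mix:")
    print(truth["category"].value_counts().to_string())
    print("effects:")
    print(truth["effect"].value_counts().to_string())
    for sample, tags in sorted(ds.tags_by_sample.items()):
        print(f"{sample}: {len(tags)} tags ({ds.condition_by_sample[sample]})")


if __name__ == "__main__":
    main()
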