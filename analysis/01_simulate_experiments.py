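"""Simulate the two temperature regimes of the experiment.

Generates one cold-regime and one hot-regime Evolve-and-Resequence
experiment at study-condition defaults (5 replicates each, census 1000,
replicate-specific Ne, Pool-seq at ~80x of generations 0-51 / 0-59) and
writes sync, founder VCF, sample annotations and the ground truth under
results/data/<regime>/.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from acehap.io_formats import write_haplotype_vcf, write_json, write_sync, \
    write_table
from acehap.synthetic import cold_config, hot_config, simulate_experiment

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    for factory in (cold_config, hot_config):
        config = factory(seed=SEED)
        exp = simulate_experiment(config)
        outdir = ROOT / config.regime
        outdir.mkdir(parents=True, exist_ok=True)
        write_sync(exp.counts, outdir / "poolseq.sync")
        write_haplotype_vcf(exp.founder, outdir / "founder_haplotypes.vcf")
        write_table(pd.DataFrame(
            [dataclasses.asdict(s) for s in exp.counts.samples]),
            outdir / "sample_annotations.csv")
        write_table(exp.sampled_class_frequencies(),
                    outdir / "true_class_frequencies.csv")
        write_json(dataclasses.asdict(exp.truth), outdir / "truth.json")
        print(f"{config.regime}: {exp.counts.n_sites} SNPs x "
              f"{exp.counts.n_samples} Pool-seq samples, "
              f"{exp.founder.n_haplotypes} founder haplotypes "
              f"-> {outdir}")


if __name__ == "__main__":
    main()
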