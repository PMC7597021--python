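"""Haplotype-class frequency trajectories from Pool-seq marker medians.

For each regime: parse the sync file, filter SNPs (minor allele count
>= 5, coverage >= 10 in every sample), take the median class-1-allele
frequency over usable markers and the median of the three resistance
allele frequencies, and derive (f_1a, f_1b, f_2) per replicate and
generation.  Writes tidy tables and a mean-trajectory figure per regime.
"""

from pathlib import Path

import pandas as pd

from acehap.haplotype_classes import MarkerSet
from acehap.io_formats import read_json, read_sync, read_table, write_table
from acehap.io_formats import SampleInfo
from acehap.plots import trajectory_plot
from acehap.trajectories import class_frequencies, filter_snps

ROOT = Path(__file__).resolve().parents[1] / "results"


def load_regime(regime: str):
    data = ROOT / "data" / regime
    annot = [SampleInfo(str(r.replicate), int(r.generation), str(r.regime))
             for r in read_table(data / "sample_annotations.csv").itertuples()]
    table = read_sync(data / "poolseq.sync", annot)
    truth = read_json(data / "truth.json")
    return table, truth


def main() -> None:
    markers = MarkerSet(read_table(ROOT / "tables" / "marker_snps.csv"))
    for regime in ("cold", "hot"):
        table, truth = load_regime(regime)
        filtered, report = filter_snps(table, min_mac=5, min_coverage=10)
        sites = table.sites
        res = sites[sites["pos"].isin(truth["resistance_positions"])]
        res = pd.DataFrame({"chrom": res["chrom"], "pos": res["pos"],
                            "resistance_nuc": res["alt"]})
        traj = class_frequencies(filtered, markers, res)
        n_used = traj.table["n_markers_used"].iloc[0]
        print(f"{regime}: {len(report.excluded)} SNPs filtered, "
              f"{traj.n_markers_dropped} markers dropped regime-wide, "
              f"{n_used} markers used")
        last = traj.table[traj.table["generation"]
                          == traj.table["generation"].max()]
        print(f"  final mean frequencies: "
              f"1a {last['f_1a'].mean():.3f}, 1b {last['f_1b'].mean():.3f}, "
              f"2 {last['f_2'].mean():.3f}")
        write_table(traj.table,
                    ROOT / "tables" / f"class_trajectories_{regime}.csv")
        figdir = ROOT / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        trajectory_plot(traj.table,
                        figdir / f"class_trajectories_{regime}.png",
                        title=f"{regime} regime")


if __name__ == "__main__":
    main()
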