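"""Simulate the three synthetic libraries used throughout the analysis.

Writes, at the study's reported conditions:
  * a 100,000-pair bulk amplicon library at the published junction mixture,
  * a plasmid control library (contiguous, unspliced templates),
  * a 50-cell UMI-tagged single-cell library (Poisson means 64 linear /
    11 circular molecules per cell, 3-30 reads per molecule).

FASTQ files go to scratch/ (they are large and regenerable); ground-truth
tables go to results/.
"""

from pathlib import Path

from circamp import (
    SimulationConfig,
    bulk_study_config,
    simulate_bulk_amplicons,
    simulate_plasmid_amplicons,
    simulate_single_cell_reads,
    single_cell_study_config,
    synthetic_locus,
    write_pairs,
)
from circamp.locus import write_locus

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    locus = synthetic_locus()
    write_locus(locus, SCRATCH / "locus.fa", SCRATCH / "exons.tsv")
    print(f"locus: {len(locus.sequence)} nt, exons "
          f"{[(e.exon_id, e.start, e.end) for e in locus.exons]}")

    pairs, truth = simulate_bulk_amplicons(locus, bulk_study_config(seed=SEED))
    write_pairs(pairs, SCRATCH / "bulk_R1.fastq.gz", SCRATCH / "bulk_R2.fastq.gz")
    truth.reads.to_csv(SCRATCH / "bulk_truth.tsv.gz", sep="\t", index=False)
    print(f"bulk: {len(pairs)} pairs; isoform tally:")
    print(truth.reads["isoform"].value_counts().to_string())

    pairs, truth = simulate_plasmid_amplicons(
        locus, SimulationConfig(n_reads=2000, seed=SEED)
    )
    write_pairs(pairs, SCRATCH / "plasmid_R1.fastq.gz",
                SCRATCH / "plasmid_R2.fastq.gz")
    print(f"plasmid control: {len(pairs)} pairs")

    pairs, truth = simulate_single_cell_reads(
        locus, single_cell_study_config(seed=SEED + 1)
    )
    write_pairs(pairs, SCRATCH / "sc_R1.fastq.gz", SCRATCH / "sc_R2.fastq.gz")
    truth.cells.to_csv(RESULTS / "sc_cell_truth.tsv", sep="\t", index=False)
    means = truth.cells.groupby("isoform")["molecules"].mean()
    print(f"single-cell: {len(pairs)} pairs across 50 cells; "
          f"true per-cell means: {means.round(2).to_dict()}")


if __name__ == "__main__":
    main()
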