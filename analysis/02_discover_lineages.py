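"""Run the full discovery pipeline on the simulated genome.

Protein search with the reference transposase panel, HSP merging, flank
extraction, clean-dataset filtering, greedy clustering, consensus building
(with TSD-calibrated element ends), Tc1 exclusion, consensus-driven second
pass, structural annotation and MITE sublineage grouping, decay and
insertion-site statistics, and LTT dynamics. Results land in results/run/.
"""
from pathlib import Path

from marinerscape.pipeline import PipelineConfig, run_all

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    genome = BASE / "sim" / "genome.fasta"
    if not genome.exists():
        raise SystemExit("run analysis/01_simulate_genome.py first")
    cfg = PipelineConfig(genome_paths=(str(genome),),
                         out_dir=str(BASE / "run"), seed=42)
    res = run_all(cfg)
    s = res.summary
    print(f"{s['n_first_pass_hits']} first-pass HSPs -> "
          f"{s['n_first_pass_copies']} copies -> {s['n_clusters']} clusters "
          f"-> {s['n_lineages']} mariner lineages "
          f"({s['n_tc1_excluded']} Tc1-like excluded)")
    print(f"clean dataset: {s['n_copies_clean']} copies; "
          f"{s['n_mites']} MITE copies in {s['n_mite_sublineages']} sublineage(s)")
    for row in s["lineage_table"]:
        print(f"  {row['lineage']:10s} {row['subfamily']:11s} "
              f"n={row['n_copies']:3d}  2TIR={row['n_two_tir']:3d}  "
              f"ORF={row['n_coding']:3d}  div={row['mean_divergence']:.4f}  "
              f"size={row['mean_size']:.0f}")


if __name__ == "__main__":
    main()
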