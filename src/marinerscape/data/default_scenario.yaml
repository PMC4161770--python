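# Default simulation scenario: a 2 Mb background genome (40% GC) carrying
# three mariner lineages at different life-cycle stages:
#   marA - old amplification burst (age 0.25 sim units) with a MITE
#          sublineage born by a 774-nt internal deletion of its 1300-nt
#          master (526-nt derivative), strong TA-flank A/T bias, plus
#          planted segmental duplications;
#   marB - recent burst (age 0.10), unbiased insertion;
#   marC - ongoing burst (rate still rising at present).
# substitution_rate 0.3/unit keeps within-lineage identity above the 0.80
# clustering threshold while burst ages stay on the stated scale; truth
# burst ages in divergence units are substitution_rate * age.
genome_length: 2000000
gc_content: 0.40
seed: 42
total_time: 0.30
dt: 0.0025
max_copies: 2000
min_site_separation: 600
scaffold_id: contig1
lineages:
  - name: marA
    master_length: 1300
    rate: {kind: burst, center_age: 0.25, width: 0.03, height: 60.0}
    substitution_rate: 0.3
    internal_deletion_rate: 1.2
    deletion_mean_nt: 80.0
    truncation_rate: 0.4
    truncation_mean_nt: 150.0
    insertion_rate: 0.5
    insertion_mean_nt: 8.0
    mite_event: {time: 0.035, type: deletion, start: 263, end: 1037}
    flank_at_bias: 0.8
    segmental_duplications: 4
    panel_reference: Mos1
    panel_divergence: 0.15
    min_copies: 40
    max_lineage_copies: 170
    require_mite_copies: 12
  - name: marB
    master_length: 1286
    rate: {kind: burst, center_age: 0.10, width: 0.025, height: 65.0}
    substitution_rate: 0.3
    internal_deletion_rate: 1.0
    deletion_mean_nt: 80.0
    truncation_rate: 0.3
    truncation_mean_nt: 150.0
    insertion_rate: 0.4
    insertion_mean_nt: 8.0
    flank_at_bias: 0.5
    panel_reference: syn_mell1
    panel_divergence: 0.12
    min_copies: 40
    max_lineage_copies: 160
  - name: marC
    master_length: 1286
    rate: {kind: ongoing, base: 3.0, width: 0.04, height: 55.0}
    substitution_rate: 0.3
    internal_deletion_rate: 0.8
    deletion_mean_nt: 80.0
    truncation_rate: 0.2
    truncation_mean_nt: 150.0
    insertion_rate: 0.3
    insertion_mean_nt: 8.0
    flank_at_bias: 0.65
    panel_reference: syn_dros1
    panel_divergence: 0.12
    min_copies: 25
    max_lineage_copies: 120
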