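# Annotated pipeline configuration (coalisle pipeline --config this.yaml)

# --- input data ------------------------------------------------------------
# Either point at observed files ...
# fasta: data/mt.fasta          # aligned mtDNA FASTA (equal-length records)
# genepop: data/strs.genepop    # microsatellite genotypes (2/3-digit alleles)
# popmap: data/popmap.tsv       # copy<TAB>population assignments
# ... or generate a study-shaped synthetic dataset with recorded truth:
synthetic: true
# Optional overrides for the synthetic design (defaults match the study
# shape: 97 island strains, 565 bp, 16 STR loci):
# synthetic_design:
#   n_mt: {A: 58, B: 29, C: 163, D: 33, a: 22, b: 29, c: 30, d: 16}
#   locus_length: 565
#   n_str_loci: 16

# --- ABC settings ----------------------------------------------------------
# priors_file: priors.yaml      # PriorSpec YAML; omitted = documented defaults
n_per_scenario: 500             # simulations per scenario in the reference table
tolerance: 0.01                 # retained fraction for rejection
staged: false                   # true = two half-batches, then a top-k final
top_k: 6                        # finalists kept in staged mode
n_scenarios: null               # cap the 24 enumerated scenarios (testing only)
n_pods: 0                       # >0 enables confidence + bias/precision QC

# --- mismatch-distribution settings ---------------------------------------
mmd_n_boot: 1000                # parametric bootstrap replicates per population
mu_site: 7.6e-08                # substitutions per site per generation
gens_per_year: 1.0              # generations per year for tau -> years
rounding: 1000                  # round expansion dates to the nearest N years
island_populations: [a, b, c, d]

# --- reproducibility -------------------------------------------------------
seed: 1                         # global seed; outputs embed it with the config hash
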