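# shredsim

Stochastic, individual-based simulation of chromosome-shredding CRISPR homing
gene drives in a closed pest-mouse population.

The model couples demography (discrete breeding cycles, a polygyny-capped
mating system, density-dependent logistic survival) with drive genetics
(germline homing with multiplexed gRNAs under simultaneous cutting,
NHEJ-derived resistance alleles with optional span deletions, coding vs
non-coding cassette placement, zygotic Y-shredding that converts XY males to
sub-fertile XO females). A Y-linked X-shredding comparator strategy and a
global sensitivity analysis (Latin hypercube sampling + boosted-regression-tree
emulation) are included.

## Model in one paragraph

Each breeding cycle runs five stages: (i) every female samples a mate
uniformly from the pool of males with remaining capacity (at most `f_max`
females per male); (ii) mated females produce Poisson(`litter_mean`) litters
(scaled by `xo_fertility` for XO mothers); (iii) per conception, germline
homing is resolved in drive-heterozygous parents (each susceptible site cut
with probability `p_c`; a cut repairs by homing with probability `1 - p_n`,
otherwise NHEJ mutates all cut sites and deletes the sequence between the
outermost cuts), alleles and allosomes transmit Mendelian (with an X bias
`p_x_xo` in XO mothers), YO conceptions die, XY drive carriers are shredded
to XO with probability `p_y`, and under coding placement any inherited
non-functional allele is embryonic-lethal; (iv) everyone (newborns included)
survives with probability `s(N) = 1/(1+exp(a+bN))`, calibrated so a drive-free
population is stationary at `k` and grows at `exp(r_max)` per year at low
density; (v) survivors age one cycle.

## CLI

```bash
# one replicate, baseline parameters
shredsim simulate --k 10000 --inoculum-size 100 --p-y 1.0 --seed 1 --out run/

# replicate batch with trajectory summaries (and optional plot)
shredsim replicates --replicates 100 --p-y 0.75 --f-max 3 --out run/ --plot

# minimum Y-shredding efficiency for certain eradication
shredsim threshold --f-max 3 --placement coding --p-nf 1 --py-grid 0.5:1.0:0.01 \
    --replicates 30 --out threshold.json

# scaled-down global sensitivity analysis
shredsim sensitivity --n-samples 5000 --scaled --seed 1 --out sens/
```

Flags mirror the model symbols one-to-one (`--p-c`, `--p-n`, `--n-guides`,
`--p-nf`, `--p-y`, `--xo-fertility`, `--p-x-xo`, `--f-max`, `--litter-mean`,
`--r-max`, `--k`, `--years`, `--replicates`, `--seed`, `--placement`,
`--strategy`, and `--p-x`, `--p-y-yo` for the X-shredder). The same names are
accepted as keys of a flat YAML/JSON file passed via `--config`; CLI flags
override file values, unknown keys are an error, and every run writes a
`manifest.json` from which `shredsim.io.replay` reproduces the outputs
bitwise.

Trajectory CSVs are tidy with columns
`replicate, year, cycle, N, XX, XY, XO, WW, WG, GG, WR, GR, RR, eradicated`
(cycle 0 is the initial census; allosome and autosome genotype counts each sum
to N on every row; allele letters: W wildtype, R resistant, G drive).

## Layout

- `src/shredsim/params.py` — parameter dataclasses (each model symbol lives in
  exactly one place)
- `src/shredsim/drive_genetics.py` — allele state machine, exact homing
  transition tables (2^s subset enumeration), gamete sampling, Y-shredding
- `src/shredsim/population.py` — packed structure-of-arrays population
- `src/shredsim/demography.py` — mate allocation, litters, logistic survival
- `src/shredsim/engine.py` — five-stage cycle, replicates, threshold search
- `src/shredsim/xshredder.py` — Y-linked X-shredder comparator
- `src/shredsim/sensitivity.py` — LHS design, BRT emulator, partial
  dependence, convergence diagnostics
- `src/shredsim/io.py`, `cli.py`, `plotting.py` — config/CSV/JSON/manifest
  plumbing, click CLI, optional plots
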