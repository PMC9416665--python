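# idrmem

Residue-specific membrane-association propensities of intrinsically
disordered protein regions (IDRs), predicted from sequence alone.

Each residue `n` receives a statistical weight that is the product of
contributing factors from every site in the sequence (plus optional
terminal pseudo-sites): a factor starts at a charge-class amplitude at
sequence distance 0 and decays toward 1 with distance,

```
w_n = prod_i [ 1 + (q_cls(i) - 1) / (1 + a_cls(i) |i-n| + b_cls(i) |i-n|^2) ]
P_n = c * w_n / w_max
```

with three charge classes — positive (K, R, and a free N-terminus),
negative (D, E, and a free C-terminus), neutral (everything else).  Two
published amplitude sets ship with the package: `disordered`
(q+ = 2.43, q− = 0.26, q0 = 0.59) and `helix` (q+ = 2.29, q− = 0.64,
q0 = 1.17); distance constants are a± = 0.0982, b± = 0.00305,
a0 = 0.521.  Weights are accumulated in log space.

The package also provides:

- **zmap** — the smooth map from side-chain tip heights above the
  membrane phosphate plane to contact probabilities (a logistic whose
  width itself interpolates between 1.2 and 3.2 Å).
- **toy** — the seven-residue moving-average-charge baseline plus an
  ordinary-least-squares comparator against observed contact profiles.
- **fitting** — optimization of the three amplitudes against observed
  contact-probability profiles (per-protein scale `c` profiled out in
  closed form, seeded multi-start L-BFGS-B), per-protein RMSE, pooled
  R0², and grouped leave-one-out robustness analysis.
- **synthetic** — random IDR-like sequences of controlled charge
  composition and model-derived noisy contact profiles, so everything is
  testable offline.
- **io** — FASTA/TSV readers and writers and a composite amide
  chemical-shift-perturbation helper
  (`sqrt(dH² + weight·dN²)`, weight defaulting to 0.154).

## CLI

```bash
idrmem predict --fasta seqs.fasta --mode disordered --termini free --offset 580 --out profile.tsv
idrmem fit     --profiles profiles/ --fasta seqs.fasta --seed 1 --groups groups.json --loo --out fit.json
idrmem ztip2c  --in ztip.tsv --out contact.tsv
idrmem toy     --fasta seqs.fasta --window 7 --out toy.tsv
idrmem synth   --spec spec.json --outdir synth/
idrmem csp     --in shifts.tsv --nitrogen-weight 0.154 --floor 0.005 --out csp.tsv
```

Profile TSVs are tab-separated with a `#`-prefixed header and columns
`index, residue, class, weight, propensity`.  Indices are 1-based over
the supplied sequence; `--offset` adds a constant to map onto author or
UniProt numbering.  `--termini free` (default) models the terminal
charges as extra pseudo-sites co-located with the first and last
residues; `capped` disables them.  The parameter set is user-selected
(`--mode`), not auto-detected.

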