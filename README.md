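# acehap

Haplotype-class selection analysis for Evolve-and-Resequence (E&R)
Pool-seq experiments, built around the *Ace* insecticide-resistance
locus of *Drosophila simulans*.

## The problem

*Ace* encodes acetylcholinesterase, the target of organophosphate and
carbamate insecticides. A haplotype carrying the three linked
resistance mutations I161V, G265A and F330Y segregates at high
frequency in natural populations, and its fitness **cost** in an
insecticide-free environment — and how that cost depends on ambient
temperature — can be measured by experimental evolution: evolve
replicate populations from one founder at two temperature regimes,
Pool-sequence them at several generations, and track how fast the
resistance haplotype is lost.

The key design feature is the founder's haplotype structure at *Ace*:

* **class 1a** — a recently swept, nearly monomorphic haplotype class
  carrying all three resistance mutations;
* **class 1b** — its sister class, identical background without the
  resistance mutations;
* **class 2** — a diverse susceptible class with ~20× the nucleotide
  diversity of class 1.

Because 1a and 1b differ essentially only by the resistance triple, the
contrast of their selection coefficients, `s_1a − s_1b`, isolates the
cost of the resistance mutations from the genetic background.

`acehap` implements the full downstream pipeline for this design, plus
a synthetic-data generator that emulates the entire experiment with
known truth so every estimator can be validated end to end.

## What the package computes

| stage | module | method |
|---|---|---|
| founder class calling | `acehap.haplotype_classes` | exclusion of failed crosses and class-1/2 recombinants; agglomerative clustering on shared polymorphisms; 1a/1b split by the resistance triple |
| diagnostic markers | `acehap.haplotype_classes` | SNPs fixed-different between retained class-1 and class-2 haplotypes |
| nucleotide diversity | `acehap.haplotype_classes` | π = (mean pairwise difference d̄ᵢⱼ) / L, L = 36,265 bp (*Ace* gene) |
| class trajectories | `acehap.trajectories` | per sample, f₁ = median marker frequency, f₁ₐ = median of the three resistance-allele frequencies, f₁ᵦ = f₁ − f₁ₐ (clamped), f₂ = 1 − f₁ |
| temporal Ne | `acehap.inference` | F̄_c = mean (x−y)²/(z(1−z)) corrected for two-stage Pool-seq sampling; Ne = −t / (2 ln(1 − F_corr)) |
| selection coefficients | `acehap.inference` | least-squares fit of the co-dominant (h = 0.5) Wright–Fisher recursion p′ = p(p(1+s)+q(1+hs))/w̄; marginal per-class fits and a joint three-class fit |
| SNP scan | `acehap.inference` | classic Cochran–Mantel–Haenszel χ² and a drift-aware score test with null variance z(1−z)[1−(1−1/2Ne)ᵗ + sampling terms] |
| LD50 | `acehap.dose_response` | probit GLM, P(death) = Φ(a + b·log₁₀ dose), LD50 = 10^(−a/b) with a delta-method CI |
| synthetic experiments | `acehap.synthetic` | founder construction, diploid WF drift at Ne with per-class fitness, binomial pool + Poisson/binomial read sampling, probit bioassays |

## Worked example

Run the numbered analysis scripts in order (each is a thin driver over
the library and writes its tables under `results/`):

```bash
python analysis/01_simulate_experiments.py    # cold + hot regimes
python analysis/02_call_haplotype_classes.py
python analysis/03_class_trajectories.py
python analysis/04_selection_coefficients.py
python analysis/05_cmh_scan.py
python analysis/06_dose_response.py
python analysis/07_calibration.py
```

Output of steps 02 and 04 on the default simulation (seed 0):

```
class counts: {'1a': 19, '2': 5, '1b': 8, 'excluded:recombinant': 2, 'excluded:homozygous': 2}
retained: 32 of 36 haplotypes
marker SNPs between class 1 and class 2: 166
pi(class 1) = 0.0004 (n = 27, L = 36265)
pi(class 2) = 0.0083 (n = 5, L = 36265)

cold: Ne from neutral panels [202, 251, 251, 211, 156] (simulated at [209, 255, 259, 198, 175])
  joint    s_1a - s_1b = -0.0546 (SEM 0.0145; truth -0.0550)
hot:
  joint    s_1a - s_1b = -0.0271 (SEM 0.0186; truth -0.0310)
```

Reading: of 36 experimentally derived founder haplotypes, 4 are
excluded (2 failed crosses, 2 recombinants); the remaining 32 split
19/8/5 into classes 1a/1b/2 with the expected 20-fold diversity
contrast, and 166 marker SNPs separate class 1 from class 2. The
resistance triple is strongly counter-selected in the cold regime
(ŝ ≈ −0.055 per generation) and about half as costly in the hot regime
— the estimates recover the simulated truths within the drift-limited
replicate scatter (SEM ≈ 0.015).

Step 05 reproduces a subtle and instructive artefact: although the
resistance triple is the causal target, the SNP-level scan ranks the
class-1 marker SNPs *above* the resistance sites, because the diverse
susceptible class 2 outcompetes both class-1 subgroups. Selection in
structured populations is more reliably read at the haplotype level
than SNP by SNP.

A command-line interface mirrors the pipeline
(`acehap simulate | classes | trajectories | ne | selection | cmh | ld50`);
see `acehap --help`.

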