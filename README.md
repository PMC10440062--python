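# gmrepro

**Operator error and reproducibility in landmark-based geometric
morphometrics.**

When several people digitise the same photographs of live animals —
here, the motivating system is Atlantic salmon (*Salmo salar*) smolts
photographed in the field and landmarked by four independent operators —
each operator places "the same" landmarks slightly differently. This
systematic digitisation bias can rival the biological signal of
interest. `gmrepro` implements the full analysis stack needed to
quantify that error and to decide whether a biological result (for
example a between-river difference in body shape) survives it:

- **Superimposition.** Generalised Procrustes analysis (partial
  Procrustes: translation, unit-centroid-size scaling, rotation without
  reflection) with sliding semi-landmarks under the minimum Procrustes
  distance criterion, polynomial *unbending* of body-arching artefacts
  through landmarks that lie on a naturally straight axis, and
  IQR-based outlier screening.
- **Shape statistics.** PCA; between-group PCA (bgPCA) with
  leave-one-out cross-validated classification; Procrustes ANOVA with
  the randomised residual permutation procedure (RRPP; sequential SS,
  `F = (SS/df) / (SS_res/df_res)`, `Z = standardised log F`); allometry
  adjustment by regression of shape on log centroid size; paired
  Hotelling *T*² tests between operators and between digitisation
  trials; angles between shape-change vectors with the exact
  `sin^(p-2)θ` null; bootstrap confidence intervals for group mean
  distances; repeatability (ICC, `R = s²_A / (s²_A + s²_W)` from
  one-way Procrustes ANOVA mean squares); and a nested variance
  partition (individual / individual:operator / residual).
- **Synthetic data.** A generator that emulates the study design —
  22 landmarks (15 fixed + 7 semi-landmarks) on a salmonid template,
  two populations with a small mean-shape difference, four operators
  with head-concentrated systematic bias, small trial noise, allometry,
  per-specimen body arching and a random photographic embedding — with
  the complete ground truth retained for recovery tests.
- **Pipeline.** A five-test assessment (operator mean shapes; group
  differences per operator; consistency of group differences; the risk
  of cross-merging datasets digitised by different operators;
  intra-operator error) runnable from Python or the command line, with
  TPS-dialect file IO.

## Worked example

```python
import gmrepro as g

spec = g.SyntheticSpec(seed=42)                      # two rivers, four operators
dataset, truth = g.simulate_dataset(spec)
report = g.run_assessment(dataset, g.AssessmentConfig.fast(seed=42))

print(f"specimens analysed: {report.preliminary['n_specimens']}")
print(f"operator LOO classification accuracy: {report.test1['cv_accuracy']:.1%}")
row = report.test1["pairwise"][0]
print(f"{row['Comparison']}: distance {row['Euclidean dist.']:.5f}, "
      f"T2 {row['T2']:.0f}, p = {row['P']:.2g}")
for op, t in report.test2["river_anova"].items():
    print(f"{op}: river r2 = {t['r2']:.4f}, F = {t['F']:.2f}, p = {t['P']:.4f}")
```

prints

```
specimens analysed: 284
operator LOO classification accuracy: 97.7%
Op.1 vs Op.2: distance 0.01117, T2 42436, p = 6.9e-248
Op.1: river r2 = 0.0329, F = 9.61, p = 0.0010
Op.2: river r2 = 0.0337, F = 9.84, p = 0.0010
Op.3: river r2 = 0.0317, F = 9.22, p = 0.0010
Op.4: river r2 = 0.0323, F = 9.41, p = 0.0010
```

Reading: the four operators produce mean shapes so distinct that
specimens can be assigned to their digitiser with 97.7 % accuracy and
every pairwise operator comparison is overwhelmingly significant
(systematic inter-operator bias) — yet all four operators still detect
the same small between-river shape difference (r² ≈ 3 % of shape
variation, p = 0.001, the permutation floor at 999 permutations). The
intra-operator side of the same report shows repeatability ≈ 0.91 per
operator, and the nested partition attributes ~66 % of shape variation
in the replicate subset to individuals, ~30 % to inter-operator error
and ~4 % to trial-to-trial noise.

The same pipeline runs from the shell:

```bash
gmrepro simulate --seed 42 -o fixtures/
gmrepro assess fixtures/ -o report/ --seed 42 --profile fast
```

which writes `report/report.json` (authoritative, byte-reproducible
given the seeds), `report/report.md` and the aligned coordinates as
CSV. Real TPS files digitised with tpsDig can be superimposed with
`gmrepro gpa <files...> --scheme scheme.yaml -o aligned.csv`.

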