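# phenocage

Behavioral phenotyping of mice from long home-cage recordings and
walkway (CatWalk-style) gait sessions, built for studies that compare
genotypes, ages and drug treatments — e.g. the 3xTg-AD Alzheimer's model
against wild-type controls, with candidate therapeutics.

The pipeline consumes three data streams and produces one behavioral
profile per experimental group:

1. **Pose tables** (DeepLabCut wide-CSV dialect: per-frame x, y,
   likelihood for 12 body parts) from a 22-hour, 1 frame/s home-cage
   assay with day/night phases and three visual-stimulus presentations.
   Entries with likelihood < 0.90 are masked and interpolated.  From the
   filtered tracks two fixed batteries are computed per animal: a
   15-parameter *track* battery (movement, acclimation, habituation,
   quadrant occupancy) and a 52-parameter *pose* battery (speed classes
   — scoot / burst / escape —, stretch-attend posture, sociability at
   the cage window, stimulus responses).
2. **Syllable label sequences** (per-frame integer codes from an
   unsupervised segmentation such as Keypoint-MoSeq, consumed rather
   than fitted) over a 29-syllable codebook, summarized as per-syllable
   bout frequency and mean duration, assay-wide and per 10-minute
   period (the three stimulus onsets fall in periods 73, 85 and 97).
3. **Footfall records** (timestamped paw contacts with print geometry
   and intensity), filtered for compliant runs — one-directional
   crossings completed in under 10 s — and reduced to the standard gait
   battery: print length, toe spreads, intensities, stand / step cycle,
   the seven-way support decomposition, base of support, cadence,
   number of steps and %NSSP (normal step sequence patterns, the six
   canonical quadruped orders Aa/Ab/Ca/Cb/Ra/Rb matched up to the
   starting paw).

The group profiles (15 + 52 + 29 + 29 = **125 named parameters**) are
z-scored, weighted by the absolute PC1 loadings of a PCA over the profile
matrix, and clustered with Ward's method on Euclidean distances; the
dendrogram is exportable as Newick and cut into k = 3 flat clusters.
Group comparisons use Shapiro–Wilk gating, two-way ANOVA (age × genotype)
with Tukey HSD, the exact unpaired Wilcoxon rank-sum test, and
Kruskal–Wallis with Dunn's post-hoc, rendered as a significance matrix of
stars and direction arrows.

A fully seeded synthetic-cohort generator (`phenocage.synth`) emulates the
assay — semi-Markov activity with phase modulation, correlated random-walk
trajectories, a rigid 12-keypoint body template, stimulus responses with
habituation, semi-Markov syllable sequences, and walkway runs with
group-dependent effects — so every pipeline stage has a parameter-recovery
test surface.

## Worked example

```python
from phenocage import (CohortConfig, simulate_cohort, filter_low_likelihood,
                       battery_track15, battery_pose52, assemble_profiles,
                       pca_weights, weighted_ward, animal_summary)

cfg = CohortConfig(n_per_group=3, duration_hours=2.0, seed=42)
recs, seqs, runs = simulate_cohort(cfg)

track, pose = [], []
for rec in recs:
    f = filter_low_likelihood(rec)          # mask likelihood < 0.90
    track.append(battery_track15(f))
    pose.append(battery_pose52(f))

profiles = assemble_profiles(track, pose, seqs)
loadings, evr, weights = pca_weights(profiles)
result = weighted_ward(profiles, weights, k=3)
print(f"profiles: {profiles.shape[0]} groups x {profiles.shape[1]} parameters")
print(f"PC1+PC2 explained variance: {100 * evr[:2].sum():.1f}%")
```

prints, for this 2-hour desk-scale cohort:

```
profiles: 10 groups x 125 parameters
PC1+PC2 explained variance: 47.2%
```

and the k = 3 cut of the weighted Ward dendrogram places the old
untreated AD-model group with the young cabozantinib-treated group
(cluster 1), the young WT/control-like groups together (cluster 2), and
the old WT group with the old drug-treated groups (cluster 3) — the
planted structure of the generator's default effect table.  The gait
battery on the same cohort recovers the planted effects:

```
NSSP% young WT: 100.0, young AD: 58.4
hindpaw intensity old AD / young WT: 1.30
```

A command-line interface wraps the same stages:

```bash
phenocage simulate --seed 1 --outdir data/
phenocage extract  --indir data/ --outdir out/
phenocage gait     --indir data/ --outdir out/
phenocage profile  --indir data/ --outdir out/   # profiles, weights, Newick
phenocage stats    --indir data/ --outdir out/ --group-a AD_O --group-b WT_O
```

## Layout

| module                | contents                                              |
|-----------------------|-------------------------------------------------------|
| `phenocage.assay`     | timeline/geometry types, pose-table I/O, likelihood filter |
| `phenocage.homecage`  | track15 and pose52 feature batteries                  |
| `phenocage.syllables` | bout statistics, per-period summaries, transitions    |
| `phenocage.gait`      | compliance filter, Table-style gait battery, NSSP     |
| `phenocage.profiles`  | 125-column profiles, PCA weights, weighted Ward       |
| `phenocage.stats`     | ANOVA/Tukey, Wilcoxon, Kruskal–Wallis/Dunn, reporting |
| `phenocage.synth`     | seeded synthetic cohorts with known group effects     |
| `phenocage.cli`       | `phenocage` command-line entry point                  |

See `docs/methods.md` for the modeling choices, parameter defaults and
known limitations.
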