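# facespace

Cross-property face-space analysis: does a representational space
organized for one facial property already support the others?

Face perception must read out *invariant* properties of a face —
identity, sex, race — and *variant* ones, above all facial expression.
A long-standing question in computational cognitive neuroscience is
whether these are handled by one representational system or by separate
ones.  `facespace` operationalizes the question with a linear model:
train an Eigenface/Fisherface subspace on one property, relabel the
projected samples by another property, and measure how well the new
labeling clusters — scored by a delayed-match-to-sample (DMS) distance
rule and by within/between-class distance statistics.  High transfer
(e.g. identity-trained → sex-tested, ID:SE) argues for shared
representation; collapse to chance (e.g. identity-trained →
expression-tested, ID:EX) argues for separation.

The package is aimed at researchers in face perception and
representation learning who want a tested, seeded, end-to-end
implementation of this protocol, driven by a synthetic face-image
generator (the original face databases are private), with every stage
exposed as a library function.

## The model

Images `x ∈ R^8100` (90×90, grayscale) are centered on the mean face
and reduced by PCA to `k` components.  For a labeling with `C` classes,
the Linear Fisher Discriminant solves the generalized eigenproblem

    S_B v = λ S_W v ,   m = min(C − 1, k) directions,

with `S_B` the between-class scatter of class means and `S_W` the
pooled within-class scatter (ridge-regularized).  Directions keep the
generalized-eigenvector normalization `vᵀ S_W v = 1`, so the projection
whitens within-class scatter and Euclidean distances count within-class
noise units.  Subspaces of different `C` are padded to a common
dimension with random directions orthonormal in the `S_W` metric.  A
DMS trial draws two references from different classes and a probe from
one of them; the trial is correct iff the probe is strictly nearer its
own class's reference.  Percent correct is enumerated over all valid
(pair, probe) triples (uniformly sampled above 100 000 triples).
Within/between per-sample average distances are compared with a
one-sided two-sample Kolmogorov–Smirnov test ("between" > "within"),
and conditions are compared with pooled two-sample t-tests
(`df = n₁ + n₂ − 2`).  See `docs/methods.md` for the full account.

## Worked example

```python
from facespace import ConditionSpec, pipeline, run_condition

# the two default synthetic collections: 120 identities x 5 viewpoints
# (balanced sex x race) and 50 identities x 6 expressions (frontal)
datasets = pipeline.build_datasets(pipeline.default_config())

for train, test, ds, faces in [
    ("sex", "sex", "invariant", 120),
    ("identity", "sex", "invariant", 120),
    ("identity", "identity", "invariant", 120),
    ("expression", "expression", "expression", 160),
    ("identity", "expression", "expression", 160),
]:
    spec = ConditionSpec(train, test, ds, n_pca_components=10,
                         n_faces=faces, seed=0)
    row = run_condition(spec, datasets[ds], target_dim=10)
    print(f"{spec.name}: {row['percent_correct']:.1f}% correct "
          f"({row['n_trials']} DMS trials), KS D={row['ks_D']:.2f}, "
          f"p={row['ks_p']:.2g}")
```

prints

```
SE:SE: 65.9% correct (52200 DMS trials), KS D=0.67, p=1.3e-12
ID:SE: 58.0% correct (52200 DMS trials), KS D=0.25, p=0.018
ID:ID: 85.3% correct (3480 DMS trials), KS D=0.87, p=1.1e-20
EX:EX: 88.5% correct (60840 DMS trials), KS D=0.95, p=1.3e-31
ID:EX: 48.3% correct (67590 DMS trials), KS D=0.06, p=0.69
```

Read the last two columns as "how strongly the *test* property clusters
in the *trained* space".  The identity-trained space supports sex
classification almost as well as the sex-trained space itself (ID:SE
tracks SE:SE; both its KS statistic and DMS score show sex structure),
but carries essentially no expression structure: ID:EX sits at chance
(48.3 %, two-alternative task) with a flat distance histogram
(D = 0.06, p = 0.69), while the expression-trained baseline EX:EX
reaches 88.5 %.  That is the headline dissociation: invariant
properties share a space; the variant property does not.

## Command line

```bash
facespace generate --out data/            # write PNG collections + labels.csv
facespace run --out results/              # full protocol: sweep, t-tests,
                                          # KS stats, notched boxplots,
                                          # face-space figures
facespace sweep --out results.csv         # sweep only
facespace report --results results.csv --out report/
```

`facespace run` sweeps every train:test condition over PCA components
[6:2:42] and face counts [20:10:120] (invariant) / [20:10:160]
(expression), omitting rows with fewer faces than components, and
writes `results.csv`, `stats.csv`, `ks_stats.csv`, `figures/` and
`run.log`.  All outputs are bit-reproducible given the configured base
seed (YAML config via `--config`).

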