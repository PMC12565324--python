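# morphocavity

Geometric morphometrics of unilateral nasal-cavity surfaces: template-based
semi-landmark transfer with thin-plate-spline (TPS) bending-energy sliding,
Generalized Procrustes Analysis (GPA), shape PCA with elbow retention and
resampling stability, Ward/HCPC morphotype clustering with automatic cluster
count, and full statistical cluster characterization (per-landmark MANOVA,
per-axis ANOVA, pairwise Tukey HSD, Lin's CCC repeatability, chi-square and
Kruskal–Wallis demographics, permutation Procrustes ANOVA for bilateral
symmetry). A parametric synthetic-cavity generator makes the entire pipeline
testable end to end without any external data.

## Layout

| Module | Role |
| --- | --- |
| `morphocavity.geometry_io` | Mesh (STL ASCII/binary, ASCII PLY) and landmark (CSV, LM3 text) I/O, mirroring, exact closest-point-on-mesh queries |
| `morphocavity.tps` | 3D thin-plate-spline fitting/evaluation and the bending-energy matrix |
| `morphocavity.sliding` | Template-to-specimen semi-landmark transfer and tangent-plane sliding by bending-energy minimization |
| `morphocavity.procrustes` | Centroid size, pairwise alignment, GPA, Procrustes distance, Goodall-F permutation ANOVA |
| `morphocavity.shape_stats` | Shape PCA, elbow/stability analyses, Ward tree + inertia-gain cluster count + index vote, MANOVA/ANOVA/Tukey, Lin's CCC, count tests |
| `morphocavity.cohort` | Specimen exclusions, patient-level cluster pairing, at-least-one membership, demographics tables |
| `morphocavity.synthetic` | Parametric half-shell cavity surfaces, the 210-landmark template, and seeded morphotype populations |
| `morphocavity.pipeline` / `morphocavity.cli` | Config-driven end-to-end orchestration with deterministic JSON/CSV reports |

## CLI

```sh
# end-to-end run from a YAML config (synthetic or file-backed data)
morphocavity run --config cfg.yaml

# generate a synthetic population as STL + CSV artifacts
morphocavity synth --spec spec.yaml --out population/ --seed 7

# materialize the small deterministic dataset used by the test suite
morphocavity fixtures --out fixtures/
```

A minimal config:

```yaml
seed: 7
output_dir: out
data:
  kind: synthetic
  n_patients: 45
hcpc:
  kmin: 2
  kmax: 10
```

Exit codes: 0 ok, 1 configuration error, 2 compute error. The same config
and seed produce a byte-identical `report.json`.

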