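# fdcdiff

Fragment-based dual conditional diffusion for pocket-conditioned 3D
molecular generation.

Structure-based drug design often starts from a known fragment bound in a
protein pocket and asks: how should it grow into a full drug-like ligand?
`fdcdiff` answers with two conditional denoising-diffusion stages over 3D
point clouds of typed atoms. Stage 1 grows a **scaffold** around the
fragment's anchor atoms (the cleavage sites that mark valid growth
positions), conditioned on the pocket G^P, the fragment F, and its anchor
set A. Stage 2 decorates the scaffold with an **R-group**, conditioned on
(G^P, G^S), using virtual-atom padding so variable-size R-groups (up to 10
atoms) fit one tensorial shape. The two stages are trained separately,
each with its own parameters — decoupled training keeps the scaffold loss
from dominating.

A molecule is G = (x, r) with one-hot atom types x ∈ {0,1}^{n×f} and
coordinates r ∈ ℝ^{n×3}. The forward chain is the variance-preserving

    q(x_t | x_{t-1}) = N(x_t; sqrt(1-β_t) x_{t-1}, β_t I),

with β_t linear from 1e-4 to 0.02 (scaffold stage) or derived from a
squared-polynomial ᾱ_t schedule (R-group stage). The reverse chain is
ε-parameterized: an E(3)-equivariant graph network predicts the injected
noise ε̂ = [ε̂_r, ε̂_h] from the noisy atoms plus the frozen context, and
training minimizes E‖ε − ε̂‖². Equivariance is by construction — feature
updates consume only scalars (embeddings, squared distances, Gaussian RBF
expansions of distances), coordinate updates are linear in relative
positions, and context atoms receive exactly zero coordinate update.

Generated atom clouds have no bonds; a learned edge-focused refinement
network classifies every atom pair within 3 Å into {single, double,
aromatic, triple, none}, with a deterministic covalent-radius rule as
fallback and training oracle. An evaluation battery scores the results:
QED, normalized synthetic accessibility, logP, Lipinski compliance,
Tanimoto diversity/similarity, the atomic-composition R value, and KL
divergence between geometric feature distributions.

Everything is testable at desk scale: a built-in catalog of ideal-geometry
molecules plus pseudo-atom pocket shells supplies synthetic
protein–ligand complexes, so no external data is needed.

## Worked example

```python
import numpy as np
from fdcdiff import chem_data as cd
from fdcdiff.diffusion_core import make_schedule
from fdcdiff.egnn_denoiser import DenoiserConfig
from fdcdiff.generator import (TrainConfig, scaffold_example,
                               train_stage, generate_scaffold)

# synthetic complex: ethanol ligand, 16-atom pocket shell at 6 Å
pocket, ligand, fragment, scaffold, rgroup = cd.make_toy_complex(
    cd.ToyComplexSpec("ethanol", seed=1))

ex = scaffold_example(pocket, fragment, scaffold)   # one training tuple
sched = make_schedule("linear", 100)
model, losses = train_stage(
    [ex],
    TrainConfig("scaffold", learning_rate=1e-3, batch_size=8,
                iterations=1500, seed=0),
    sched,
    denoiser_config=DenoiserConfig(n_layers=3, hidden_dim=64, K=16))
print(f"final loss {np.mean(losses[-50:]):.3f}")

state = generate_scaffold(ex.context, model, sched, n_new=1, seed=0)
rmsd = np.sqrt(np.mean(np.sum(
    (state.atoms.coords - scaffold.coords) ** 2, axis=1)))
print(f"scaffold RMSD vs fixture: {rmsd:.2f} Å,"
      f" elements {state.atoms.symbols}")
```

prints (exact loss varies slightly with BLAS):

```
final loss 0.060
scaffold RMSD vs fixture: 0.06 Å, elements ['C', 'C']
```

i.e. after overfitting the single toy complex, the reverse chain rebuilds
the missing scaffold atom from pure noise to within a few hundredths of
an ångström, with the right element. The same protocol drives the R-group stage.

The command line runs the whole pipeline:

```bash
fdc demo --out runs/demo --seed 0
# prep -> train x2 -> sample -> bonds -> eval; writes runs/demo/report.json
```

The demo is byte-reproducible: two runs with the same seed produce
identical SDF outputs, manifests and reports.

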