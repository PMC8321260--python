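# metaseg

Optimization-based meta-learning domain adaptation for few-shot medical
image segmentation.

Segmenting a new tissue type usually fails for lack of annotated scans.
One remedy is to *learn the initialization*: meta-train a segmentation
network across several well-annotated source tissues so that a few gradient
steps on a handful of target examples produce a usable model.  `metaseg`
implements an interpolation meta-update built for exactly this setting,
together with the MAML and Reptile baselines it extends, a compact U-Net, a
class-weighted Dice metric, a staged layer-freezing transfer schedule, and
a synthetic tissue-task generator so every component runs and is tested
without downloading any data.

## The algorithm

With θ the network's parameter vector, α the inner learning rate, β the
outer step size and L_τ the cross-entropy loss on a sampled batch τ, one
meta-iteration is

    τ_s ~ p(T)                                # support batch, whole pool
    θ′_i = θ′_{i−1} − α ∇L_{τ_s}(θ′_{i−1}),   i = 1..k
    τ_q ~ p(T)                                # query batch, same pool
    θ′  = θ′_k − α ∇L_{τ_q}(θ′_k)
    θ   ← θ + β (θ′ − θ)

Unlike MAML, support and query batches are drawn from the *entire* example
distribution — no support/query partition — so the initialization learns
from the full diversity of each tissue's location, size, shape and signal
intensity.  Unlike Reptile, the final step is taken on an independent
batch, which injects a gradient-alignment term −α·E[L″_q L′_s] into the
expected update (see `metaseg.gradient_analysis`, which makes that Taylor
analysis executable and testable).  Defaults: α = 1e-3, β = 0.4, k = 3,
batch size 6 with class equipartition.

Segmentation quality is the class-weighted Dice coefficient

    DSC = Σ_k 2 ω_k Σ_i p(k,i) g(k,i) / (Σ_i p(k,i)² + Σ_i g(k,i)²),

with ω = 0.9 on the target tissue and 0.1 on background, reported next to
foreground precision and recall, as mean ± 95% CI over five runs.

## Worked example

Meta-learn an initialization on three synthetic source tissue classes, then
transfer it to a held-out target class from 30 examples with the depth-2
layer-freezing schedule:

```python
import numpy as np
from metaseg import MetaConfig, meta_train
from metaseg.segmodel import (SegmentationObjective, UNet, UNetSpec,
                              calibrate_bn_stats, fine_tune_layer_freezing,
                              make_freeze_plan)
from metaseg.synthetic_tasks import (augment, generate_pool, held_out_target,
                                     three_tissue_sources)
from metaseg.pipelines import evaluate_model

source = generate_pool(three_tissue_sources(), 40, np.random.default_rng(0), size=32)
target_train = generate_pool([held_out_target()], 30, np.random.default_rng(1), size=32)
target_test = generate_pool([held_out_target()], 40, np.random.default_rng(2), size=32)

model = UNet(UNetSpec.tiny(), np.random.default_rng(3))
theta, history = meta_train(
    model.get_flat(), source, "ours", MetaConfig(), n_iterations=200,
    rng=np.random.default_rng(4), objective=SegmentationObjective(model),
)
model.set_flat(theta)
calibrate_bn_stats(model, source.examples, np.random.default_rng(5))
print(f"meta-training support loss: {history['loss_support'][0]:.1f} -> {history['loss_support'][-1]:.1f}")
print(f"zero-shot target DSC {evaluate_model(model, target_test).dsc:.3f}")

plan = make_freeze_plan(2, n_epochs_per_stage=10, n_down_blocks=2)
fine_tune_layer_freezing(model, plan, target_train.examples,
                         np.random.default_rng(6), augment_fn=augment)
rec = evaluate_model(model, target_test)
print(f"target DSC {rec.dsc:.3f}  precision {rec.precision:.3f}  recall {rec.recall:.3f}")
```

Output:

```
meta-training support loss: 907.4 -> 16.0
zero-shot target DSC 0.740
target DSC 0.846  precision 0.804  recall 0.894
```

The support loss falling by ~50× shows the initialization adapting to the
source family; a zero-shot DSC of 0.74 on a tissue class never seen during
meta-training, rising to 0.85 after 30 epochs on 30 examples (versus ~0.7
when the same budget starts from random initialization), is the few-shot
transfer effect the method exists for.  Swap `"ours"` for `"maml"` or
`"reptile"` to run the baselines; `metaseg.pipelines.run_transfer_benchmark`
runs all arms with matched seeds.

A CLI wraps the same functions: `metaseg synth`, `metaseg meta-train`,
`metaseg finetune`, `metaseg evaluate`, `metaseg ablate-depth`,
`metaseg analyze-taylor`.  Medical Segmentation Decathlon volumes can be
loaded through `metaseg.synthetic_tasks.load_decathlon_slices` (NIfTI,
never required for tests).

## Layout

- `metaseg.metrics` — weighted DSC, precision/recall, loss, run statistics
- `metaseg.meta_optim` — episodic sampling, the three meta-update rules
- `metaseg.gradient_analysis` — trajectory/Taylor/Monte-Carlo analysis
- `metaseg.segmodel` — numpy U-Net, freezing plans, training loops
- `metaseg.synthetic_tasks` — tissue-task generator, augmentation, NIfTI adapter
- `metaseg.pipelines` — the three training pipelines, evaluation, ablation
- `docs/methods.md` — model assumptions, parameter choices, limitations
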