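# graphadt

Interpretable prediction of **acute dermal toxicity (ADT)** — a binary,
molecule-level endpoint describing adverse effects of short-term skin
exposure — for small molecules given as SMILES strings.

Most molecular graph classifiers pass messages between atoms and summarise
the graph with uniform pooling, which blurs the chemistry that actually
drives toxicity: particular **bonds** and the functional groups they form
(nitro, trichloromethyl, esters, ...). This package centres the model on
bonds instead:

1. **Structure remapping.** The directed molecular graph *G* = ⟨*X*, *E*, *A*⟩
   (atom features *X*, per-arc bond features *E*, adjacency *A*) is lifted
   to a bond graph *G*ʳ = (*X*ʳ, *E*ʳ, *A*ʳ): every directed arc *u*→*v*
   becomes a node with features *X·u* ‖ *E·u,v* ‖ *X·v*, every consecutive
   arc pair ("bond–atom–bond" path) *u*→*v*→*z* becomes an edge with
   features *E·u,v* ‖ *X·v* ‖ *E·v,z*, and *A*ʳ·uv,vz = 1 iff
   *A·u,v* = *A·v,z* = 1 — a directed line-graph construction with
   concatenated features.
2. **Multi-view pooling (MVPool).** Each encoder layer (a GIN message-passing
   step) is followed by pooling that scores node importance from three
   views — structure p_c = σ(α·log(deg+ε)+β), features p_f = σ(MLP(Z)),
   and a personalised-PageRank structure–feature view
   p_cf = σ(δ(I−(1−δ)Ã)⁻¹ PR) — fuses them with adaptive attention into a
   convex combination p, and keeps the top ⌈r·N⌉ nodes, multiplicatively
   gated by σ(p) so selection stays differentiable.
3. **Contrastive two-stream training.** Both the original and the remapped
   graph are encoded; a symmetric NT-Xent loss aligns the two views of each
   molecule against in-batch negatives while a binary cross-entropy head on
   the concatenated representations predicts toxicity.
4. **Shapley bond attribution.** Each undirected bond is a player in a
   cooperative game whose value function is the model's toxicity
   probability with the other bonds masked in the remapped graph; Shapley
   values (exact for ≤ 6 bonds, Monte-Carlo permutations otherwise) flag
   key bonds at a threshold (default 0.2) and match them to named
   functional-group SMARTS patterns.

The model is exposed as a scikit-learn estimator (`GraphADTClassifier` with
`fit` / `predict` / `predict_proba`), so it composes with sklearn pipelines
and model selection. All tensor math runs on a small reverse-mode autodiff
engine over NumPy that ships with the package.

Because the public Rabbit/Rat ADT datasets are not bundled, the package
includes a synthetic-data module that plants toxicophore fragments on random
scaffolds with configurable label noise; every stage of the pipeline is
testable offline against it.

## Worked example

```python
from graphadt import (GraphADTClassifier, SynthConfig, bond_shapley,
                      generate_dataset, evaluate, parse_smiles)

df = generate_dataset(SynthConfig(n_molecules=400, label_noise=0.05, seed=7))
train, test = df.iloc[:320], df.iloc[320:]
clf = GraphADTClassifier(epochs=10, random_state=0)
clf.fit(train["smiles"].tolist(), train["label"].to_numpy())
rep = evaluate(clf, test)
print(f"AUC={rep.auc:.3f} ACC={rep.acc:.3f} MCC={rep.mcc:.3f} "
      f"SE={rep.se:.3f} SP={rep.sp:.3f}  (n={rep.n})")

smi = "CCCC(CC)C[N+](=O)[O-]"          # alkane with a planted nitro group
print("P(toxic) = %.3f" % clf.predict_proba([smi])[0, 1])
report = bond_shapley(clf, parse_smiles(smi), n_samples=200, seed=7)
for bond, value in sorted(report.values.items(), key=lambda kv: -kv[1])[:3]:
    print(f"bond {bond}: Shapley = {value:+.3f} groups={report.group_tags.get(bond, [])}")
print("flagged (threshold 0.2):", report.flagged)
```

Output:

```
AUC=0.936 ACC=0.938 MCC=0.875 SE=0.946 SP=0.930  (n=80)
P(toxic) = 0.997
bond (7, 8): Shapley = +0.332 groups=['nitro']
bond (7, 9): Shapley = +0.280 groups=['nitro']
bond (6, 7): Shapley = +0.162 groups=[]
flagged (threshold 0.2): [(7, 8), (7, 9)]
```

The held-out metrics sit near the ceiling set by the 5 % label noise
(Bayes-optimal accuracy 0.95), and the two N–O bonds of the planted nitro
group receive the largest Shapley values — the attribution recovers the
toxicophore that generated the label.

The same pipeline is available from the shell:

```bash
graphadt generate --n 1000 --seed 7 --out synth.csv
graphadt train --data synth.csv --out run/
graphadt predict --checkpoint run/checkpoint --data synth.csv --out pred.csv
graphadt explain --checkpoint run/checkpoint --smiles "CC(Cl)(Cl)Cl" --out report.json
```

## Layout

| module | contents |
| --- | --- |
| `graphadt.featurize` | SMILES → directed graph ⟨X, E, A⟩; atom/bond featurisation |
| `graphadt.remap` | structure remapping G → Gʳ |
| `graphadt.pooling` | MVPool views, attention fusion, top-rank pooling |
| `graphadt.encoder` | GIN + MVPool stack, layer readouts, multi-layer attention |
| `graphadt.model` | `GraphADTClassifier`, NT-Xent and BCE losses, persistence |
| `graphadt.explain` | Shapley bond attribution, functional-group frequency |
| `graphadt.synthdata` | planted-toxicophore dataset generator, CSV I/O |
| `graphadt.metrics` | AUC / ACC / MCC / sensitivity / specificity |
| `graphadt.cli` | `graphadt generate/train/predict/explain` |
| `graphadt.autodiff`, `graphadt.nn` | reverse-mode autodiff engine, layers, Adam |

See `docs/methods.md` for the model's assumptions, parameter defaults and
known limitations.
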