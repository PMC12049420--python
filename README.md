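# protospec

Interpretable, prototype-based classification of 1-D Raman spectra, with
transfer learning from a large inorganic (mineral-like) source domain to a
small biological target domain — the setting of ivory species identification,
where labeled spectra are scarce but open mineral spectral libraries are
huge.

## What it does

Raman spectra are biochemical fingerprints: intensity versus wavenumber shift
(cm⁻¹). Dentine — the mineralised tissue of tusks — shows bands at phosphate
(960 cm⁻¹), carbonate (1070 cm⁻¹), amide III (1240/1270 cm⁻¹) and CH₂
(1450 cm⁻¹), with inter-species differences concentrated around the 960 cm⁻¹
phosphate band. `protospec` classifies such spectra **and says why**, using
prototypes: real training spectra selected as cluster medoids in a learned
feature space.

The pipeline:

1. **Preprocess** — resample each spectrum to 950 points over 600–1640 cm⁻¹,
   min–max normalise per spectrum (or standardise per feature for the
   chemometrics baseline).
2. **Encode** — a small 1-D CNN φ(·; θ) (3 × conv–BN–ReLU–maxpool–dropout,
   adaptive pool, flatten) maps each spectrum to a 2048-D feature vector.
   The encoder is pretrained on the source domain and transferred with
   **full**, **linear** (last block only) or **no** finetuning.
3. **Prototypes** — cluster the training features (k-means, mean-shift, or
   density/typicality peaks) and keep the nearest *real sample* to each
   centroid, medoid-style.
4. **Classify** — nearest prototype:
   `ŷ = CLASS(argmin_p ‖φ(q) − φ(p)‖²)` (IDEAL-style); or a density-based
   rule system with per-class confidence
   `λ_c = max_p exp(−‖φ(q) − p‖²/σ_c²)` (xDNN-style); or the PCA→LDA
   chemometrics baseline on raw spectra.
5. **Explain** — nearest prototype per class with distances, a per-band
   radar distance table on the wavenumber grid, and a 2-D PCA/Voronoi map
   of the prototypes.

A seeded synthetic generator produces mineral-like (narrow single lines)
and ivory-like (broad overlapping bands, differing only at 960 cm⁻¹)
datasets, so the entire pipeline is testable end to end without any
external data. See `docs/methods.md` for the model details and what the
synthetic benchmark does and does not show.

## Worked example

```sh
protospec simulate --preset ivory --n-per-class 12 --seed 5 --out ivory.csv
protospec pretrain --data ivory.csv --epochs 2 --seed 1 --out enc.npz
protospec prototypes --data ivory.csv --checkpoint enc.npz --k 2 --out protos
protospec classify --data ivory.csv --method ideal --checkpoint enc.npz \
    --prototypes protos --out pred.csv
protospec crossval --data ivory.csv --method pcalda --folds 4 --out cv.csv
```

prints

```text
wrote 24 spectra (2 classes) to ivory.csv
pretrained 2 epochs; final training accuracy 0.500; checkpoint -> enc.npz
4 prototypes -> protos.json / .features.csv
wrote 24 predictions to pred.csv
pcalda: mean accuracy 1.0000 +/- 0.0000 (4 folds) -> cv.csv
```

`ivory.csv` is a matrix-dialect CSV (spectrum id, class, subclass, then one
column per wavenumber). The two-epoch pretrain is deliberately minimal — at
two epochs the in-epoch accuracy (measured with dropout active) is still at
chance; real runs use 30+ epochs and reach 1.0. The four
prototypes are actual training spectra, two medoids per class; `pred.csv`
lists, for every spectrum, the predicted class, a similarity-based
confidence, and the index of the winning prototype. The PCA/LDA baseline
separates the two synthetic classes perfectly at this noise level, as the
cross-validation summary shows.

The same machinery is available as a library:

```python
from protospec import synthetic, preprocess, prototypes, classify

data = synthetic.generate_dataset(synthetic.ivory_recipes(), 30, seed=1)
X, grid = preprocess.preprocess_dataset(data)          # (60, 950)
ps = prototypes.identify_prototypes(X, data.labels)    # k-means medoids
pred = classify.ideal_predict(X, classify.IdealModel(ps))
```

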