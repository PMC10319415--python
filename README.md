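# vityield

Early soybean-yield prediction from time-series canopy images and seed
information, built around a wide-deep transformer architecture:

- each RGB plot image is **segmented** into plant and soil streams
  (excess-green index + Otsu threshold + morphological cleanup);
- two independent **ViT encoders** extract a 128-d feature per stream and
  timestamp; the streams are fused per timestamp by an element-wise
  product;
- an **encoder-only temporal transformer** (sine/cosine positional
  encoding, 3 layers x 5 heads) turns the fused series into one image
  representation;
- a one-hot **seed-combination branch** (51 categories; treatment x
  variety x seeding rate) is embedded to 16-d and concatenated before a
  dense regression head producing yield in kg/ha.

Four baselines with the same fit/predict contract are included: CNN-LR,
CNN-LSTM, ViT-LSTM and ViT-T (VGG-16 or a small 4-block CNN backbone).
Because the original 450-plot field dataset is private, the package ships a
**synthetic plot-image generator** (green crop rows on textured soil with
perspective fore-shortening, logistic canopy growth, a linear yield model
with per-combination effects and a left-skewed yield distribution) so every
stage is testable against known ground truth.

All models run on a small numpy reverse-mode autodiff engine included in
`vityield.nn` (no deep-learning framework required); training uses Adam
(lr 0.001), MSE loss, dropout 0.25 and early stopping with patience 10.

## CLI

```bash
vityield generate --n-plots 60 --seed 7 --out data/            # synthetic dataset
vityield segment  --in data/manifest.csv --out seg/            # plant/soil/mask PNGs
vityield train    --model proposed --manifest data/manifest.csv \
                  --config cfg.yaml --out run/                 # checkpoint + metrics
vityield evaluate --checkpoint run/proposed.npz --manifest data/manifest.csv
vityield analyze-seed --checkpoint run/proposed.npz \
                  --manifest data/manifest.csv --out seed/     # 51-combo counterfactuals
vityield describe --manifest data/manifest.csv                 # yield skewness/kurtosis
```

`--model` accepts `proposed`, `cnn_lr`, `cnn_lstm`, `vit_lstm`, `vit_t`;
`--small-backbone` swaps VGG-16 for the desk-scale CNN. Run configs are
YAML (see `vityield.cli_io.RunConfig`); every artifact-producing command
logs seed, config hash and timings to `log.jsonl` in its output directory.

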