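"""Regenerate src/mixirt/data/generating_parameters.csv.

Hand-transcribed population parameters of the three-class rmGPCM and mPCM
(5 items, 11 categories).  `italic` marks the five steps per (class, item)
retained in the 6-category conditions; `low_confidence` flags cells whose
typography in the source table was ambiguous.
"""
import hashlib
import pathlib

import pandas as pd

# (values[10], italic steps 1-based, low-confidence steps)
RMGPCM = {
    (1, 1): ([-0.98, 0.77, 0.52, 0.08, 1.22, -0.61, 0.78, 0.24, -1.24, 1.89], {1, 3, 5, 9, 10}, set()),
    (1, 2): ([-0.79, 0.71, -0.07, 0.03, 1.26, -1.04, 0.56, 0.96, -0.69, 2.49], {1, 3, 5, 9, 10}, set()),
    (1, 3): ([-0.28, 1.07, 0.56, 0.07, 1.76, -0.32, 0.81, 0.62, -0.94, 2.05], {1, 3, 5, 9, 10}, set()),
    (1, 4): ([-0.31, 1.98, 0.66, 0.39, 1.97, -0.55, 0.88, 0.75, -1.43, 2.27], {1, 3, 5, 9, 10}, set()),
    (1, 5): ([-0.52, 1.00, 0.32, 0.28, 1.63, -1.12, 1.21, 0.67, -0.95, 2.43], {1, 3, 5, 9, 10}, set()),
    (2, 1): ([2.27, 1.52, 0.86, 0.40, 0.64, 0.25, 0.46, 0.10, -1.92, -1.16], {1, 3, 6, 8, 9}, set()),
    (2, 2): ([1.72, 1.21, 0.83, -0.03, 0.82, 0.04, 0.59, 0.70, -0.67, -0.21], {1, 3, 4, 6, 9}, set()),
    (2, 3): ([-3.10, 4.00, 1.80, 0.58, 1.05, 0.38, 0.68, 0.45, -1.38, -1.20], {2, 3, 4, 6, 9}, set()),
    (2, 4): ([4.00, 3.28, 1.70, 1.07, 1.05, 0.28, 0.59, 0.06, -2.21, -1.73], {1, 3, 6, 8, 9}, set()),
    (2, 5): ([1.91, 1.86, 0.98, 0.38, 0.84, 0.30, 0.59, 0.29, -0.99, -0.93], {1, 3, 4, 6, 9}, set()),
    (3, 1): ([1.61, 0.60, 0.35, -0.22, 0.83, 0.01, 0.85, 0.03, 0.11, -1.93], {1, 3, 4, 9, 10}, set()),
    (3, 2): ([0.27, 0.20, -0.43, 0.48, 1.01, -0.94, 1.58, 0.23, 0.96, -0.66], {1, 3, 6, 9, 10}, set()),
    (3, 3): ([2.27, 0.60, 0.34, -0.01, 1.06, 0.33, 0.87, 0.20, 0.96, -1.46], {1, 3, 4, 9, 10}, set()),
    (3, 4): ([4.00, 0.65, 0.79, 0.22, 1.51, 0.21, 0.63, 0.12, 0.77, -2.03], {1, 3, 6, 9, 10}, set()),
    (3, 5): ([1.15, 0.68, 0.26, 0.32, 1.04, -0.32, 0.63, 0.54, 0.78, -0.70], {1, 3, 6, 9, 10}, set()),
}
MPCM = {
    (1, 1): ([-0.87, 0.85, 0.58, 0.16, 1.25, -0.58, 0.80, 0.24, -1.26, 1.86], {1, 3, 5, 9, 10}, set()),
    (1, 2): ([-0.59, 0.94, 0.09, 0.20, 1.38, -0.94, 0.64, 1.02, -0.70, 2.43], {1, 3, 5, 9, 10}, set()),
    (1, 3): ([-0.20, 0.98, 0.59, 0.09, 1.76, -0.29, 0.80, 0.64, -0.97, 2.08], {1, 3, 5, 9, 10}, set()),
    (1, 4): ([-0.74, 1.39, 0.23, 0.00, 1.72, -0.81, 0.76, 0.72, -1.39, 2.45], {1, 3, 5, 9, 10}, set()),
    (1, 5): ([-0.67, 0.73, 0.18, 0.18, 1.53, -1.27, 1.21, 0.67, -0.95, 2.54], {1, 3, 5, 9, 10}, set()),
    (2, 1): ([2.01, 1.39, 0.94, 0.42, 0.74, 0.20, 0.48, 0.06, -1.66, -1.32], {1, 3, 6, 8, 9}, set()),
    (2, 2): ([1.96, 1.34, 1.05, 0.11, 0.98, 0.06, 0.70, 0.67, -0.55, -0.25], {1, 3, 4, 6, 9}, set()),
    (2, 3): ([0.63, 2.78, 1.58, 0.54, 1.02, 0.34, 0.68, 0.42, -1.20, -1.01], {2, 3, 4, 6, 9}, set()),
    (2, 4): ([4.00, 2.02, 1.10, 0.55, 0.76, 0.03, 0.51, 0.12, -2.12, -1.86], {2, 3, 6, 8, 9}, {4, 8}),
    (2, 5): ([1.49, 1.43, 0.73, 0.19, 0.68, 0.15, 0.55, 0.27, -0.96, -0.98], {1, 3, 4, 6, 9}, set()),
    (3, 1): ([1.73, 0.78, 0.40, -0.15, 0.80, 0.17, 0.84, 0.04, 0.01, -1.89], {1, 3, 4, 9, 10}, set()),
    (3, 2): ([0.47, 0.44, -0.35, 0.71, 1.07, -0.69, 1.46, 0.27, 0.86, -0.74], {1, 3, 6, 9, 10}, set()),
    (3, 3): ([2.27, 0.59, 0.29, -0.13, 1.26, 0.37, 0.91, 0.29, 0.93, -1.53], {1, 3, 4, 9, 10}, set()),
    (3, 4): ([4.17, 0.13, 0.16, -0.34, 1.56, 0.18, 0.65, 0.33, 0.95, -1.68], {1, 3, 4, 9, 10}, {6}),
    (3, 5): ([0.90, 0.51, -0.13, 0.29, 1.27, -0.37, 0.63, 0.68, 0.94, -0.56], {1, 3, 6, 9, 10}, set()),
}
DISC = {"rmGPCM": [1.0, 0.71, 1.27, 2.57, 1.76], "mPCM": [1.0] * 5}
TRAIT_SCALE = {"rmGPCM": [0.21, 0.24, 0.21], "mPCM": [0.28, 0.30, 0.28]}
CLASS_LOGIT = {"rmGPCM": [0.0, 0.20, -0.18], "mPCM": [0.0, 0.30, -0.25]}


def main():
    rows = []
    for model, table in (("rmGPCM", RMGPCM), ("mPCM", MPCM)):
        for (g, i), (vals, italics, lowconf) in sorted(table.items()):
            assert len(vals) == 10 and len(italics) == 5
            for s, v in enumerate(vals, start=1):
                rows.append((model, g, i, s, "delta_beta", v,
                             int(s in italics), int(s in lowconf)))
        for i, v in enumerate(DISC[model], start=1):
            rows.append((model, 0, i, 0, "item_discrimination", v, 0, 0))
        for g, v in enumerate(TRAIT_SCALE[model], start=1):
            rows.append((model, g, 0, 0, "trait_scale", v, 0, 0))
        for g, v in enumerate(CLASS_LOGIT[model], start=1):
            rows.append((model, g, 0, 0, "class_logit", v, 0, 0))
    df = pd.DataFrame(rows, columns=["model", "class", "item", "step",
                                     "parameter_type", "value", "italic",
                                     "low_confidence"])
    out = pathlib.Path(__file__).resolve().parents[1] / "src" / "mixirt" / "data"
    out.mkdir(parents=True, exist_ok=True)
    path = out / "generating_parameters.csv"
    df.to_csv(path, index=False, float_format="%.2f")
    print(path, hashlib.sha256(path.read_bytes()).hexdigest())


if __name__ == "__main__":
    main()
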