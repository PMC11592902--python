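"""cytorl: hybrid CNN-ViT cytology image classification with deep-Q-learning
class reweighting.

The package generates synthetic single-cell cytology images with controllable
class imbalance, trains a compact convolutional/vision-transformer classifier
augmented by a Conv3D + BiLSTM + attention "supporter" pathway, and wraps the
training loop in a reinforcement-learning environment whose agent adjusts
per-class loss weights to improve minority-class recall.
"""

__version__ = "0.1.0"

from . import (backbone, config, data, experiments, manifest, metrics, model,
               nn, pipeline, rl, supporter, synthetic, vit)

__all__ = [
    "backbone", "config", "data", "experiments", "manifest", "metrics",
    "model", "nn", "pipeline", "rl", "supporter", "synthetic", "vit",
]
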