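"""Optional adapter exposing a pretrained AlexNet through the surrogate contract.

Import requires torch/torchvision; the rest of the package never imports this
module unless :func:`advrep.model.load_alexnet_adapter` is called.
"""

from __future__ import annotations

import numpy as np
import torch  # noqa: F401 - hard requirement of this module only
import torch.nn.functional as F
from torchvision.models import alexnet

from .model import ActivationStack, FeatureExtractor


class AlexNetAdapter(FeatureExtractor):
    input_shape = (227, 227, 3)

    def __init__(self):
        self._net = alexnet(weights="IMAGENET1K_V1").eval()

    def _prep(self, image: np.ndarray) -> "torch.Tensor":
        x = torch.as_tensor(np.asarray(image, dtype=np.float32) / 255.0)
        x = x.permute(2, 0, 1)[None]
        mean = torch.tensor([0.485, 0.456, 0.406]).view(1, 3, 1, 1)
        std = torch.tensor([0.229, 0.224, 0.225]).view(1, 3, 1, 1)
        return (x - mean) / std

    def _stage_outputs(self, x):
        feats = self._net.features
        # torchvision indices ending each conv stage (after relu/pool)
        bounds = {2: "L1", 5: "L2", 7: "L3", 9: "L4", 12: "L5"}
        acts = {}
        for i, layer in enumerate(feats):
            x = layer(x)
            if i in bounds:
                acts[bounds[i]] = x
        x = torch.flatten(self._net.avgpool(x), 1)
        cls = self._net.classifier
        acts["L6"] = F.relu(cls[1](cls[0](x)))
        acts["L7"] = F.relu(cls[4](cls[3](acts["L6"])))
        logits = cls[6](acts["L7"])
        return acts, logits

    def forward_with_activations(self, image: np.ndarray) -> ActivationStack:
        with torch.no_grad():
            acts, logits = self._stage_outputs(self._prep(image))
            probs = torch.softmax(logits, dim=1)[0].numpy()
        per_stage = {k: v.flatten().numpy() for k, v in acts.items()}
        per_stage["L8"] = probs.copy()
        return ActivationStack(per_stage=per_stage, probabilities=probs, top1=int(probs.argmax()))

    def input_gradient(self, image: np.ndarray, class_id: int) -> np.ndarray:
        x = self._prep(image).requires_grad_(True)
        _, logits = self._stage_outputs(x)
        prob = torch.softmax(logits, dim=1)[0, class_id]
        prob.backward()
        g = x.grad[0].permute(1, 2, 0).numpy()
        std = np.array([0.229, 0.224, 0.225])
        return g / (std * 255.0)
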