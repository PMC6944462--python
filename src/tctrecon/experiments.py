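"""The reference desk-scale experiment: dataset, training, evaluation.

One function runs the full pipeline at the 64 x 64 desk scale — 20 training
and 5 test phantoms, scan range [0°, 120°], 300 SART sweeps, U-net depth 3 /
base 8 trained for 40 epochs — and reports per-image PSNR/SSIM for the SART
inputs and the SARTConvNet outputs on the held-out phantoms.  Both the test
suite and the acceptance script drive this entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import TCTParams
from .metrics import psnr, ssim
from .recon import SARTConfig
from .simulate import DatasetPair, NoiseModel, build_dataset, desk_scale_params
from .unet import TrainConfig, TrainedDenoiser, UNetConfig, build_unet, train

__all__ = ["DeskExperimentResult", "run_desk_experiment"]


@dataclass
class DeskExperimentResult:
    params: TCTParams
    train_pairs: list[DatasetPair] = field(repr=False)
    test_pairs: list[DatasetPair] = field(repr=False)
    model: TrainedDenoiser = field(repr=False)
    sart_psnr: list[float] = field(default_factory=list)
    net_psnr: list[float] = field(default_factory=list)
    sart_ssim: list[float] = field(default_factory=list)
    net_ssim: list[float] = field(default_factory=list)

    @property
    def mean_sart_psnr(self) -> float:
        return float(np.mean(self.sart_psnr))

    @property
    def mean_net_psnr(self) -> float:
        return float(np.mean(self.net_psnr))


def run_desk_experiment(
    seed: int = 0,
    n_train: int = 20,
    n_test: int = 5,
    scan_range: float = 120.0,
    n_pixels: int = 64,
    sart_iterations: int = 300,
    epochs: int = 40,
    noise: NoiseModel | None = None,
) -> DeskExperimentResult:
    """Generate data, train the denoiser, evaluate on the held-out split."""
    params = desk_scale_params(n_pixels)
    train_pairs, test_pairs = build_dataset(
        n_train,
        n_test,
        scan_range=scan_range,
        noise=noise,
        sart_cfg=SARTConfig(n_iterations=sart_iterations),
        master_seed=seed,
        params=params,
    )
    model = build_unet(UNetConfig(depth=3, base_channels=8), seed=seed)
    model = train(
        model,
        train_pairs,
        test_pairs,
        TrainConfig(
            epochs=epochs,
            patch_size=n_pixels,
            lr_start=0.5,
            lr_end=0.05,
            momentum=0.99,
            grad_clip=None,
            seed=seed,
        ),
    )
    result = DeskExperimentResult(params, train_pairs, test_pairs, model)
    for pair in test_pairs:
        out = model.apply(pair.input_image)
        result.sart_psnr.append(psnr(pair.input_image, pair.label_image))
        result.net_psnr.append(psnr(out, pair.label_image))
        result.sart_ssim.append(ssim(pair.input_image, pair.label_image))
        result.net_ssim.append(ssim(out, pair.label_image))
    return result
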