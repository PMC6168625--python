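"""Orchestration of the basic and revised tracing schemes.

`run_basic` is the plain pipeline: (optional) deconvolution → single-seed
tracing → SWC.  `run_revised` inserts the mask-based AND/EOR separation before
tracing and re-merges the partial reconstructions.  Every run produces a
manifest recording inputs, parameters and outputs so a rerun is
bitwise-reproducible.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .maskops import trace_separated
from .metric import MatchResult, MetricParams, diadem_score
from .morpho import NeuronTree, read_swc, write_swc
from .stack import ImageStack, generate_psf, deconvolve, read_mask, read_stack
from .trace import TraceConfig, trace_stack

log = logging.getLogger("arborsplit")

__all__ = ["RunManifest", "run_basic", "run_revised", "evaluate"]


@dataclass
class RunManifest:
    scheme: str
    inputs: dict[str, list[str] | str]
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    software_version: str = __version__

    def record(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.log.append(f"{stamp} {message}")
        logging.getLogger("arborsplit").info(message)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class DeconvolutionConfig:
    enabled: bool = False
    na: float = 0.8
    wavelength: float = 0.488
    iterations: int = 20


def _load_and_preprocess(
    image_path, spacing, deconv: DeconvolutionConfig | None, manifest: RunManifest
) -> ImageStack:
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(f"input stage: no such image {image_path}")
    stack = read_stack(image_path, spacing=spacing)
    manifest.record(f"read stack {image_path} shape={stack.shape}")
    if deconv and deconv.enabled:
        psf = generate_psf(spacing=stack.spacing, na=deconv.na, wavelength=deconv.wavelength)
        stack = deconvolve(stack, psf, iterations=deconv.iterations)
        manifest.record(f"deconvolved ({deconv.iterations} Richardson-Lucy iterations)")
    return stack


def run_basic(
    image_path,
    out_swc,
    config: TraceConfig | None = None,
    spacing=(1.0, 0.36, 0.36),
    deconv: DeconvolutionConfig | None = None,
) -> tuple[Path, RunManifest]:
    """Basic scheme: deconvolve (optional) → trace → SWC."""
    config = config or TraceConfig()
    manifest = RunManifest(
        scheme="basic",
        inputs={"image": str(image_path)},
        config={"trace": asdict(config), "spacing": list(spacing),
                "deconvolution": asdict(deconv) if deconv else None},
    )
    stack = _load_and_preprocess(image_path, spacing, deconv, manifest)
    tree = trace_stack(stack, config)
    manifest.record(f"traced {len(tree)} nodes")
    tree.metadata["scheme"] = "basic"
    write_swc(tree, out_swc)
    manifest.outputs["swc"] = str(out_swc)
    manifest.record(f"wrote {out_swc}")
    return Path(out_swc), manifest


def run_revised(
    image_path,
    mask_paths,
    out_swc,
    config: TraceConfig | None = None,
    spacing=(1.0, 0.36, 0.36),
    deconv: DeconvolutionConfig | None = None,
) -> tuple[Path, RunManifest]:
    """Revised scheme: separate with masks → trace partials → merge → SWC."""
    if not mask_paths:
        raise ValueError("the revised scheme requires at least one mask")
    config = config or TraceConfig()
    manifest = RunManifest(
        scheme="revised",
        inputs={"image": str(image_path), "masks": [str(m) for m in mask_paths]},
        config={"trace": asdict(config), "spacing": list(spacing),
                "deconvolution": asdict(deconv) if deconv else None},
    )
    stack = _load_and_preprocess(image_path, spacing, deconv, manifest)
    masks = []
    for mp in mask_paths:
        mask = read_mask(mp, spacing=spacing)
        if mask.shape != stack.shape:
            raise ValueError(
                f"separation stage: mask {mp} shape {mask.shape} != image {stack.shape}"
            )
        masks.append(mask)
    manifest.record(f"separating with {len(masks)} mask(s)")
    tree = trace_separated(stack, masks, config)
    manifest.record(f"traced+merged {len(tree)} nodes")
    write_swc(tree, out_swc)
    manifest.outputs["swc"] = str(out_swc)
    manifest.record(f"wrote {out_swc}")
    return Path(out_swc), manifest


def evaluate(
    test_swc,
    gold_swc,
    params: MetricParams | None = None,
    report_path=None,
) -> MatchResult:
    """Score a test SWC against a gold SWC; optionally write a TSV match table."""
    test = read_swc(test_swc)
    gold = read_swc(gold_swc)
    result = diadem_score(test, gold, params)
    if report_path is not None:
        import pandas as pd

        pd.DataFrame(result.rows).to_csv(report_path, sep="\t", index=False)
    return result
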