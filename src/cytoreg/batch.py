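"""Batch-level registration via internal standards or batch consensus samples.

Batch effects are estimated once per batch — by registering the batch's
internal standard (an aliquot of a single cryopreserved sample run with every
batch) to a reference template — and the resulting per-iteration movement
vectors are frozen in a :class:`BatchTemplate` and replayed on every sample in
the batch.  Because the vectors are derived from the standard, not from the
samples themselves, the correction removes batch variation while leaving
within-batch biological differences intact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fcs
from .clusters import ClusterTemplate, assign, fit_template
from .fcs import Sample, concatenate
from .registration import (
    MovementVectors,
    RegistrationConfig,
    RegistrationLog,
    displace_events,
    register,
)

__all__ = [
    "BatchTemplate",
    "build_batch_template",
    "apply_batch_template",
    "register_study",
    "load_manifest",
]


@dataclass
class BatchTemplate:
    """Frozen registration trajectory of one batch's standard.

    ``iterations`` holds the (method, fraction, MovementVectors) captured
    while registering the batch standard to the reference template.  The
    reference batch's own template is the identity (all vectors ≈ 0).
    """

    batch_id: str
    iterations: list[tuple[str, float, MovementVectors]]
    reference_id: str = ""

    def max_displacement(self) -> float:
        """Largest single captured vector component (cumulative proxy)."""
        if not self.iterations:
            return 0.0
        return max(float(np.abs(v.masked()).max()) for _, _, v in self.iterations)

    def save(self, path) -> None:
        path = Path(path)
        meta = {
            "format": "cytoreg-batch-template",
            "version": 1,
            "batch_id": self.batch_id,
            "reference_id": self.reference_id,
            "iterations": [
                {"method": m, "fraction": f} for m, f, _ in self.iterations
            ],
        }
        path.write_text(json.dumps(meta, indent=1))
        arrays = {}
        for i, (_, _, vec) in enumerate(self.iterations):
            arrays[f"vectors_{i}"] = vec.vectors
            arrays[f"valid_{i}"] = vec.valid
        np.savez(path.with_suffix(path.suffix + ".npz"), **arrays)

    @classmethod
    def load(cls, path) -> "BatchTemplate":
        path = Path(path)
        meta = json.loads(path.read_text())
        if meta.get("format") != "cytoreg-batch-template":
            raise ValueError(f"{path} is not a cytoreg batch template")
        arrays = np.load(path.with_suffix(path.suffix + ".npz"))
        iters = []
        for i, it in enumerate(meta["iterations"]):
            vec = MovementVectors(vectors=arrays[f"vectors_{i}"], valid=arrays[f"valid_{i}"])
            iters.append((it["method"], it["fraction"], vec))
        return cls(batch_id=meta["batch_id"], iterations=iters,
                   reference_id=meta.get("reference_id", ""))


def build_batch_template(standard_sample: Sample, reference_template: ClusterTemplate,
                         config: RegistrationConfig | None = None,
                         batch_id: str = "") -> tuple[BatchTemplate, Sample, RegistrationLog]:
    """Register a batch standard to the reference template, capturing the
    per-iteration movement vectors.  Returns the template plus the registered
    standard (for QC) and the registration log."""
    captured: list = []
    registered, log = register(standard_sample, reference_template, config, capture=captured)
    template = BatchTemplate(
        batch_id=batch_id or standard_sample.source_id,
        iterations=captured,
        reference_id=str(reference_template.metadata.get("reference", "")),
    )
    return template, registered, log


def apply_batch_template(sample: Sample, batch_template: BatchTemplate,
                         reference_template: ClusterTemplate) -> Sample:
    """Replay a batch's frozen shifts on one sample.

    Per captured iteration the sample is re-assigned to the reference template
    and displaced along the *captured* vectors (never re-derived from the
    sample) with its own posteriors, at the captured fraction — so the shift
    is batch-specific, not sample-specific.
    """
    current = sample
    for method, fraction, vec in batch_template.iterations:
        a = assign(current, reference_template)
        if a.k != vec.vectors.shape[0]:
            raise ValueError(
                f"batch template ({vec.vectors.shape[0]} clusters) does not match "
                f"reference template ({a.k} clusters)"
            )
        current = displace_events(current, a.posteriors, vec, fraction)
    return current


# ---------------------------------------------------------------------------
# Whole-study driver


MANIFEST_COLUMNS = ("path", "batch", "subject", "role")


def load_manifest(path) -> pd.DataFrame:
    mf = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in mf.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    return mf


def _prepare(sample: Sample, cofactor_map=None) -> Sample:
    """Bring a raw/compensated sample to the transformed state."""
    if sample.transform_state == "raw":
        sample = fcs.compensate(sample)
    if sample.transform_state == "compensated":
        sample = fcs.arcsinh_transform(sample, cofactor_map)
    return sample


def _batch_standard(samples: dict[str, Sample], standards: dict[str, Sample],
                    batch: str, seed: int) -> tuple[Sample, bool]:
    if batch in standards:
        return standards[batch], False
    members = [s for s in samples.values()]
    n = min(s.n_events for s in members)
    warnings.warn(
        f"batch {batch!r} has no internal standard; using a consensus of its "
        f"{len(members)} samples — valid only if the batch contains a similar "
        "distribution of samples from all experimental groups",
        stacklevel=2,
    )
    return concatenate(members, n_per_sample=n, seed=seed), True


def register_batches(samples_by_batch: dict[str, dict[str, Sample]],
                     standards_by_batch: dict[str, Sample],
                     reference_batch: str,
                     k: int,
                     config: RegistrationConfig | None = None,
                     ) -> tuple[dict[str, dict[str, Sample]], dict[str, BatchTemplate], ClusterTemplate]:
    """In-memory batch registration.

    Fits the reference cluster template on the reference batch's standard (or
    consensus), builds one :class:`BatchTemplate` per batch, and replays each
    on every sample of its batch.  All samples must be transformed.
    """
    config = config or RegistrationConfig()
    if reference_batch not in samples_by_batch:
        raise ValueError(f"reference batch {reference_batch!r} not in study")
    ref_standard, _ = _batch_standard(
        samples_by_batch[reference_batch], standards_by_batch, reference_batch, config.seed
    )
    ref_template = fit_template(ref_standard, k=k, seed=config.seed)

    templates: dict[str, BatchTemplate] = {}
    registered: dict[str, dict[str, Sample]] = {}
    for batch, members in samples_by_batch.items():
        standard, is_consensus = _batch_standard(members, standards_by_batch, batch, config.seed)
        bt, _, _ = build_batch_template(standard, ref_template, config, batch_id=batch)
        if is_consensus:
            bt.reference_id += " (consensus standard)"
        templates[batch] = bt
        registered[batch] = {
            name: apply_batch_template(s, bt, ref_template) for name, s in members.items()
        }
    return registered, templates, ref_template


def register_study(manifest, config: RegistrationConfig | None = None,
                   output_dir=None, k: int = 10,
                   cofactor_map: dict[str, float] | None = None) -> dict:
    """File-level study registration driven by a manifest CSV.

    The manifest columns are path, batch, subject, role with role in
    {sample, internal_standard, reference}; the reference batch is the batch
    whose standard carries role ``reference``.  Registered FCS files are
    written next to (or under ``output_dir``) with a ``_reg`` suffix, along
    with per-batch template files and a JSON log.
    """
    config = config or RegistrationConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)

    samples_by_batch: dict[str, dict[str, Sample]] = {}
    standards_by_batch: dict[str, Sample] = {}
    reference_batch = None
    for _, row in manifest.iterrows():
        s = _prepare(fcs.read_fcs(row["path"]), cofactor_map)
        role = row["role"].strip().lower()
        batch = row["batch"]
        if role in ("internal_standard", "reference"):
            standards_by_batch[batch] = s
            if role == "reference":
                reference_batch = batch
        else:
            samples_by_batch.setdefault(batch, {})[row["path"]] = s
    if reference_batch is None:
        raise ValueError("manifest designates no reference batch (role 'reference')")
    for batch in standards_by_batch:
        samples_by_batch.setdefault(batch, {})

    registered, templates, ref_template = register_batches(
        samples_by_batch, standards_by_batch, reference_batch, k=k, config=config
    )

    outputs: dict[str, str] = {}
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref_template.save(outdir / "reference_template.json")
        for batch, bt in templates.items():
            bt.save(outdir / f"batch_{batch}_template.json")
        for batch, members in registered.items():
            for name, s in members.items():
                stem = Path(name).stem
                out_path = outdir / f"{stem}_reg.fcs"
                fcs.save_registered(s, out_path)
                outputs[name] = str(out_path)
    return {
        "registered": registered,
        "templates": templates,
        "reference_template": ref_template,
        "outputs": outputs,
    }
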