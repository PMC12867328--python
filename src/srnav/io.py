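"""Checkpointing: SR tables, codebook and optimizer state.

Arrays go into a single ``.npz`` container; scalars, hyperparameters and
provenance (config, seeds, world hashes) into a JSON sidecar next to it.
Loading restores an agent bundle exactly (weights, moments, step counter,
codebook indices), so a run can resume bit-identically given the same
derived episode seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .agent import Lesion, QModel
from .sr import EgoCodebook, SRSet


def save_checkpoint(path: str | Path, model: QModel, sr: SRSet,
                    meta: dict | None = None) -> None:
    path = Path(path)
    arrays = {
        "w_A": model.w_A, "w_E": model.w_E, "m_A": model.m_A,
        "m_E": model.m_E, "v_A": model.v_A, "v_E": model.v_E,
        "M_s_A": sr.M_s_A, "M_A": sr.M_A,
    }
    if sr.M_s_E is not None:
        arrays["M_s_E"] = sr.M_s_E
        arrays["M_E"] = sr.M_E
    if sr.codebook is not None:
        keys = [sr.codebook.view_pixels(i) for i in range(sr.codebook.n_views)]
        if keys:
            arrays["codebook_views"] = np.stack(keys)
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "t": model.t, "eta": model.eta, "beta1": model.beta1,
        "beta2": model.beta2, "eps_adam": model.eps_adam,
        "gamma_Q": model.gamma_Q, "adam_no_sqrt": model.adam_no_sqrt,
        "lesion": model.lesion.value,
        "gamma_A": sr.gamma_A, "gamma_E": sr.gamma_E,
        "alpha_A": sr.alpha_A, "alpha_E": sr.alpha_E,
        "horizon": None if sr.codebook is None else sr.codebook.horizon,
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "meta": meta or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> tuple[QModel, SRSet, dict]:
    path = Path(path)
    side = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        arrays = {k: z[k] for k in z.files}
    codebook = None
    if side["horizon"] is not None:
        codebook = EgoCodebook(side["horizon"])
        if "codebook_views" in arrays:
            for row in arrays["codebook_views"]:
                codebook.encode_key(np.ascontiguousarray(row).tobytes())
    sr = SRSet(M_s_A=arrays["M_s_A"], M_A=arrays["M_A"],
               M_s_E=arrays.get("M_s_E"), M_E=arrays.get("M_E"),
               gamma_A=side["gamma_A"], gamma_E=side["gamma_E"],
               alpha_A=side["alpha_A"], alpha_E=side["alpha_E"],
               codebook=codebook)
    model = QModel(w_A=arrays["w_A"], w_E=arrays["w_E"], m_A=arrays["m_A"],
                   m_E=arrays["m_E"], v_A=arrays["v_A"], v_E=arrays["v_E"],
                   t=side["t"], eta=side["eta"], beta1=side["beta1"],
                   beta2=side["beta2"], eps_adam=side["eps_adam"],
                   gamma_Q=side["gamma_Q"], adam_no_sqrt=side["adam_no_sqrt"],
                   lesion=Lesion(side["lesion"]))
    return model, sr, side["meta"]
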