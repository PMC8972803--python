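"""Serialization of mode sets to the documented JSON layout.

Layout (version 1): ``{"format_version": 1, "kind": "ANM|GNM|PCA",
"n_zero": int, "labels": [[chain, resnum, name], ...],
"eigenvalues": [...], "variances": [...],
"vectors": [[...mode 1...], [...mode 2...], ...]}`` — mode-major, i.e.
one inner list per mode.
"""

from __future__ import annotations

import json

import numpy as np

from .elastic import ModeSet

FORMAT_VERSION = 1


def save_modes(modes: ModeSet, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": modes.kind,
        "n_zero": int(modes.n_zero),
        "labels": [list(lab) for lab in modes.labels],
        "eigenvalues": modes.eigenvalues.tolist(),
        "variances": modes.variances.tolist(),
        "vectors": modes.vectors.T.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_modes(path) -> ModeSet:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported modes file version {payload.get('format_version')}"
        )
    return ModeSet(
        vectors=np.array(payload["vectors"], dtype=float).T,
        eigenvalues=np.array(payload["eigenvalues"], dtype=float),
        variances=np.array(payload["variances"], dtype=float),
        n_zero=int(payload["n_zero"]),
        kind=payload["kind"],
        labels=[tuple(lab) for lab in payload["labels"]],
    )
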