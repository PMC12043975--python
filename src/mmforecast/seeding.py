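"""Deterministic derivation of per-component random streams from one run seed.

Every source of randomness in the package draws from a
:class:`numpy.random.Generator` obtained here.  A single integer run seed is
expanded into independent component streams through
``SeedSequence([seed, component_id])``, where the component id is a fixed
registry entry — so adding a component never perturbs the streams of the
existing ones.
"""

from __future__ import annotations

import numpy as np

#: Fixed component registry; append only, never reorder.
_COMPONENTS = (
    "simulate",
    "missingness",
    "folds",
    "forecaster-init",
    "forecaster-train",
    "annotator-init",
    "annotator-train",
    "gibbs",
    "forecast",
    "evaluate",
)
_COMPONENT_ID = {name: i for i, name in enumerate(_COMPONENTS)}


def component_rng(seed: int, component: str, extra: int | None = None) -> np.random.Generator:
    """Generator for ``component`` under the given run seed.

    ``extra`` sub-indexes a component (e.g. one stream per fold).
    """
    try:
        cid = _COMPONENT_ID[component]
    except KeyError:
        raise KeyError(f"unknown rng component {component!r}; registry: {_COMPONENTS}")
    entropy = [int(seed), cid] if extra is None else [int(seed), cid, int(extra)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
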