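"""Genotype rate presets.

Rates live in ``data/presets.json`` (the serialized, provenance-tagged form);
:func:`make_preset` returns them as validated :class:`~cftrgate.gating.GenotypePreset`
objects.  All presets describe prephosphorylated channels gating in saturating
ATP at 25 degC.  Non-hydrolytic mutants have ``k_1 = 0`` and gate at
equilibrium between IB and B1.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .gating import GenotypePreset, RateScheme

__all__ = ["make_preset", "list_presets", "NON_HYDROLYTIC"]

# aliases tolerated on input (case-insensitive match is applied on top)
_ALIASES = {
    "E1371Q": "hE1371Q",
    "E1371S": "hE1371S",
    "K1250A": "hK1250A",
    "D1370N": "hD1370N",
    "hE1371Q_G576D": "hE1371Q_G576del",
    "hE1371S_G576D": "hE1371S_G576del",
}


@lru_cache(maxsize=1)
def _load() -> dict:
    text = resources.files("cftrgate.data").joinpath("presets.json").read_text()
    data = json.loads(text)
    data.pop("_schema", None)
    return data


def list_presets() -> list[str]:
    """Names of all documented genotypes."""
    return sorted(_load())


#: Genotypes with k_1 = 0 (computed lazily in make_preset checks).
NON_HYDROLYTIC = (
    "hE1371S", "hE1371Q", "hK1250A", "hD1370N",
    "hK1250A_E1371Q", "hD1370N_E1371Q",
    "hE1371Q_G576del", "hE1371S_G576del",
)


def make_preset(name: str, *, temperature: float = 298.15) -> GenotypePreset:
    """Return the rate scheme and provenance for a documented genotype.

    Raises ``KeyError`` listing the available presets for unknown names.
    """
    data = _load()
    canonical = _ALIASES.get(name, name)
    if canonical not in data:
        lowered = {k.lower(): k for k in data}
        canonical = lowered.get(canonical.lower(), canonical)
    if canonical not in data:
        raise KeyError(
            f"unknown genotype {name!r}; available presets: {', '.join(sorted(data))}")
    entry = data[canonical]
    scheme = RateScheme(temperature=temperature, **entry["rates"])
    return GenotypePreset(name=canonical, scheme=scheme,
                          provenance=dict(entry["provenance"]))
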