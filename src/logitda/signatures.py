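"""Registry of published immunotherapy-response gene signatures.

Only signatures whose complete gene lists are public and unambiguous are
bundled: the 8-gene T-effector (tGE8) panel and the 5-gene CD8 T-cell
activity panel.  Other widely used panels (IFN-gamma, T-cell-inflamed GEP,
TIDE T-exhaustion, PD-L1 IHC) are registered by name with their source
citation and must be supplied by the user as a JSON gene list — we do not
ship gene lists we cannot verify.
"""
from __future__ import annotations

from .datatypes import FixedSignature

_BUNDLED: dict[str, list[str]] = {
    # T-effector signature associated with PD-L1 expression and response
    # to atezolizumab (Mariathasan et al. / Necchi et al. lineage)
    "tGE8": ["IFNG", "CXCL9", "CD8A", "GZMA", "GZMB", "CXCL10", "PRF1", "TBX21"],
    # CD8+ T-cell activity markers
    "CD8T": ["CD8A", "CD8B", "GZMA", "GZMB", "PRF1"],
}

_CITED_ONLY: dict[str, str] = {
    "IFN-gamma": "18-gene IFN-gamma-related panel (Ayers et al., J Clin Invest 2017)",
    "T-inflamed": "T-cell-inflamed gene-expression profile (Cristescu et al., Science 2018)",
    "T-exhaust": "50-gene T-cell exhaustion panel (TIDE; Jiang et al., Nat Med 2018)",
    "PD-L1": "PD-L1 immunohistochemistry score (numeric covariate, not a gene list)",
}


def available_signatures() -> list[str]:
    """Names of signatures bundled with the package."""
    return sorted(_BUNDLED)


def cited_signatures() -> dict[str, str]:
    """Signatures known by citation only; user must supply the gene list."""
    return dict(_CITED_ONLY)


def get_signature(name: str) -> FixedSignature:
    if name in _BUNDLED:
        return FixedSignature(name=name, genes=list(_BUNDLED[name]))
    if name in _CITED_ONLY:
        raise KeyError(
            f"signature {name!r} is registered by citation only "
            f"({_CITED_ONLY[name]}); supply its gene list as a JSON file"
        )
    raise KeyError(f"unknown signature {name!r}; bundled: {available_signatures()}")
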