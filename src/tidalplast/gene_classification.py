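"""Classification of genes into evolutionarily divergent, concordantly plastic,
and adaptive plastic sets.

* Evolutionarily divergent (D): significantly different between tidal levels at
  0 h in *both* sites — a heritable baseline difference surviving the common
  garden.
* Concordantly plastic (P): significantly stress-responsive (6 h or 24 h vs
  0 h, populations of a site pooled) in *both* sites.
* Adaptive plastic (A): genes in both D and P, i.e. plastic genes whose
  baseline has also evolved.

The within-site combination of the two stressed times is the union by default
(evidence pooled across 6 h and 24 h); requiring significance at both times is
available via ``within_site_rule="both"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .data_model import DEResult, PipelineError
from .differential_expression import call_significant

__all__ = [
    "GeneSets",
    "evolutionarily_divergent",
    "concordantly_plastic",
    "adaptive_plastic",
    "classify_genes",
]


@dataclass
class GeneSets:
    """The three gene sets with the provenance (contrasts, thresholds) that produced them."""

    divergent: set[str]
    plastic: set[str]
    adaptive: set[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adaptive != (self.divergent & self.plastic):
            raise PipelineError("adaptive set must equal divergent & plastic exactly")

    def as_dict(self) -> dict:
        return {
            "divergent": sorted(self.divergent),
            "plastic": sorted(self.plastic),
            "adaptive": sorted(self.adaptive),
            "provenance": self.provenance,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GeneSets":
        d = json.loads(Path(path).read_text())
        return cls(
            set(d["divergent"]), set(d["plastic"]), set(d["adaptive"]),
            d.get("provenance", {}),
        )


def evolutionarily_divergent(div_site1: set[str], div_site2: set[str]) -> set[str]:
    """Genes significantly divergent between tidal levels at 0 h in both sites."""
    return set(div_site1) & set(div_site2)


def concordantly_plastic(
    plast_site1_t1: set[str],
    plast_site1_t2: set[str],
    plast_site2_t1: set[str],
    plast_site2_t2: set[str],
    within_site_rule: str = "union",
) -> set[str]:
    """Per site, combine the two stressed-time sets (union or both); intersect across sites."""
    if within_site_rule == "union":
        s1 = set(plast_site1_t1) | set(plast_site1_t2)
        s2 = set(plast_site2_t1) | set(plast_site2_t2)
    elif within_site_rule == "both":
        s1 = set(plast_site1_t1) & set(plast_site1_t2)
        s2 = set(plast_site2_t1) & set(plast_site2_t2)
    else:
        raise PipelineError(f"unknown within_site_rule {within_site_rule!r}")
    return s1 & s2


def adaptive_plastic(divergent: set[str], plastic: set[str]) -> set[str]:
    """Genes that are both evolutionarily divergent and concordantly plastic."""
    return set(divergent) & set(plastic)


def classify_genes(
    de_results: Mapping[str, DEResult],
    sites: Sequence[str],
    stress_times: Sequence[int],
    alpha: float = 0.05,
    use_adjusted: bool = True,
    within_site_rule: str = "union",
) -> GeneSets:
    """Build the three gene sets from a dict of DE results keyed by contrast name.

    Expects keys ``divergence:<site>`` and ``plasticity:<site>:<t>h`` as
    produced by :func:`tidalplast.differential_expression.standard_contrasts`.
    """
    if len(sites) != 2 or len(stress_times) != 2:
        raise PipelineError("classification expects exactly 2 sites and 2 stressed times")

    def sig(key: str) -> set[str]:
        if key not in de_results:
            raise PipelineError(f"missing DE result for contrast {key!r}")
        return call_significant(de_results[key], alpha=alpha, use_adjusted=use_adjusted)

    s1, s2 = sites
    t1, t2 = stress_times
    D = evolutionarily_divergent(sig(f"divergence:{s1}"), sig(f"divergence:{s2}"))
    P = concordantly_plastic(
        sig(f"plasticity:{s1}:{t1}h"),
        sig(f"plasticity:{s1}:{t2}h"),
        sig(f"plasticity:{s2}:{t1}h"),
        sig(f"plasticity:{s2}:{t2}h"),
        within_site_rule=within_site_rule,
    )
    A = adaptive_plastic(D, P)
    prov = {
        "contrasts": sorted(de_results),
        "alpha": alpha,
        "use_adjusted": use_adjusted,
        "within_site_rule": within_site_rule,
    }
    return GeneSets(D, P, A, prov)
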