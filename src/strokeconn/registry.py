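"""Network registry: named resting-state networks crossed with hemisphere scopes.

A registry maps network names to *base* (unlateralized) AAL3-style region
names.  Each base region resolves to a left and a right node (``PreCG_L``,
``PreCG_R``).  Crossing the networks with the requested hemisphere scopes
(``left``, ``right``, ``both``) yields the network *configurations* whose
pairwise correlation structure the connectivity module summarizes.  Under the
default six-network registry this produces 18 configurations and hence
18 + C(18, 2) = 171 connectivity predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

#: Fixed canonical ordering of hemisphere scopes.
SCOPE_ORDER = ("left", "right", "both")


@dataclass(frozen=True)
class NetworkConfiguration:
    """One network restricted to a hemisphere scope.

    ``scope == "both"`` keeps the left and right instances of every base
    region as separate nodes; interhemispheric homologue pairs therefore
    contribute to the intra-network average.
    """

    network_name: str
    scope: str
    member_regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scope not in SCOPE_ORDER:
            raise ValueError(f"unknown hemisphere scope {self.scope!r}")
        if len(self.member_regions) == 0:
            raise ValueError(
                f"configuration {self.network_name}:{self.scope} has no members"
            )

    @property
    def name(self) -> str:
        return f"{self.network_name}:{self.scope}"


class NetworkRegistry:
    """Named networks of base regions plus a lateralization map.

    Parameters
    ----------
    networks:
        Ordered mapping of network name to base region names.  Networks may
        share base regions (e.g. SFGmedial belongs to both a motor network
        and the default mode network).
    hemisphere_scopes:
        Subset of ``("left", "right", "both")``; kept in canonical order.
    lateralization:
        Optional base name -> (left label, right label).  Defaults to
        ``("<base>_L", "<base>_R")``.
    """

    def __init__(
        self,
        networks: Mapping[str, Sequence[str]],
        hemisphere_scopes: Sequence[str] = SCOPE_ORDER,
        lateralization: Mapping[str, tuple[str, str]] | None = None,
    ) -> None:
        if len(networks) == 0:
            raise ValueError("registry needs at least one network")
        names = list(networks)
        if len(set(names)) != len(names):
            raise ValueError("network names must be unique")
        bad = [s for s in hemisphere_scopes if s not in SCOPE_ORDER]
        if bad:
            raise ValueError(f"unknown hemisphere scopes: {bad}")
        self.networks: dict[str, tuple[str, ...]] = {}
        for name, bases in networks.items():
            bases = tuple(bases)
            if len(bases) == 0:
                raise ValueError(f"network {name!r} has no regions")
            if len(set(bases)) != len(bases):
                raise ValueError(f"network {name!r} lists duplicate regions")
            self.networks[name] = bases
        self.hemisphere_scopes = tuple(
            s for s in SCOPE_ORDER if s in hemisphere_scopes
        )
        if not self.hemisphere_scopes:
            raise ValueError("at least one hemisphere scope required")
        if lateralization is None:
            lateralization = {
                b: (f"{b}_L", f"{b}_R")
                for bases in self.networks.values()
                for b in bases
            }
        self.lateralization = {b: tuple(lr) for b, lr in lateralization.items()}
        for bases in self.networks.values():
            for b in bases:
                if b not in self.lateralization:
                    raise ValueError(f"region {b!r} has no lateralization entry")

    # -- enumeration ---------------------------------------------------------

    def lateralized_members(self, network: str, scope: str) -> tuple[str, ...]:
        bases = self.networks[network]
        left = tuple(self.lateralization[b][0] for b in bases)
        right = tuple(self.lateralization[b][1] for b in bases)
        if scope == "left":
            return left
        if scope == "right":
            return right
        if scope == "both":
            return left + right
        raise ValueError(f"unknown scope {scope!r}")

    def configurations(self) -> list[NetworkConfiguration]:
        """All configurations in canonical order (network order x scope order)."""
        out = []
        for name in self.networks:
            for scope in self.hemisphere_scopes:
                out.append(
                    NetworkConfiguration(
                        network_name=name,
                        scope=scope,
                        member_regions=self.lateralized_members(name, scope),
                    )
                )
        return out

    def all_regions(self) -> list[str]:
        """Every lateralized region, left then right per base, deduplicated in
        first-appearance order over networks."""
        seen: dict[str, None] = {}
        for bases in self.networks.values():
            for b in bases:
                for lab in self.lateralization[b]:
                    seen.setdefault(lab, None)
        return list(seen)

    def cache_key(self) -> tuple:
        return (
            tuple((n, m) for n, m in self.networks.items()),
            self.hemisphere_scopes,
            tuple(sorted((b, lr) for b, lr in self.lateralization.items())),
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NetworkRegistry)
            and self.cache_key() == other.cache_key()
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"NetworkRegistry({list(self.networks)}, "
            f"scopes={self.hemisphere_scopes})"
        )

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path) -> None:
        payload = {
            "networks": {n: list(m) for n, m in self.networks.items()},
            "hemisphere_scopes": list(self.hemisphere_scopes),
            "lateralization": {
                b: list(lr) for b, lr in self.lateralization.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        lat = payload.get("lateralization")
        if lat is not None:
            lat = {b: tuple(lr) for b, lr in lat.items()}
        return cls(
            networks=payload["networks"],
            hemisphere_scopes=payload.get("hemisphere_scopes", SCOPE_ORDER),
            lateralization=lat,
        )


#: The six predefined networks (AAL3 base regions): four motor networks, the
#: default mode network and the frontoparietal network.  Networks deliberately
#: share regions (SFGmedial, ACCsup, MFG, IFGoperc, ANG appear twice).
DEFAULT_NETWORKS: dict[str, tuple[str, ...]] = {
    "MotorI": ("PreCG", "PoCG", "PCL"),
    "MotorII": ("SMA", "SFG", "MFG", "IFGoperc", "ROL", "SFGmedial"),
    "MotorIII": ("INS", "ACCsup", "MCC"),
    "MotorIV": ("PUT", "PAL", "CAU"),
    "DMN": ("SFGmedial", "PCC", "ACCsub", "ACCpre", "ACCsup", "ANG", "PCUN"),
    "Frontoparietal": ("MFG", "IFGoperc", "IFGtriang", "ANG", "IPG"),
}


def default_registry() -> NetworkRegistry:
    """The default six-network registry with all three hemisphere scopes."""
    return NetworkRegistry(DEFAULT_NETWORKS)
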