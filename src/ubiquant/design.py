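"""Experimental design: samples, groups, replicates, and control roles.

A ubiquitin-pulldown experiment compares "target" sample groups (His-tagged
ubiquitin added, a stimulus applied) against two kinds of negative controls:
a *background* pulldown control (untagged ubiquitin, so nothing specific
binds the resin) and a *blocked* control (ubiquitin-activating E1 enzyme
inhibited, so no de novo conjugation occurs). The design object carries the
sample -> group mapping and which groups play which control role; every
downstream stage consults it rather than inferring structure from column
names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = ["SampleDesign"]


@dataclass(frozen=True)
class SampleDesign:
    """Sample -> group mapping with control-role assignments.

    Parameters
    ----------
    samples
        Ordered sample identifiers (one per MS run / intensity column).
    group_of
        Mapping from each sample to its experimental group.
    control_roles
        Mapping with optional keys ``background`` (untagged-ubiquitin
        pulldown control group) and ``blocked`` (E1-inhibited control
        group). Values are group names or ``None``.
    target_groups
        Ordered names of the stimulus/enriched groups. Must be disjoint
        from the control groups.
    raw_file_of
        Optional raw-file -> sample mapping used when reading evidence
        tables whose rows are keyed by MS raw-file name.
    """

    samples: tuple[str, ...]
    group_of: Mapping[str, str]
    control_roles: Mapping[str, str | None] = field(default_factory=dict)
    target_groups: tuple[str, ...] = ()
    raw_file_of: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "target_groups", tuple(self.target_groups))
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers in design")
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        extra = set(self.group_of) - set(self.samples)
        if extra:
            raise ValueError(f"group_of refers to unknown samples: {sorted(extra)}")
        controls = {g for g in self.control_roles.values() if g is not None}
        overlap = controls & set(self.target_groups)
        if overlap:
            raise ValueError(f"groups cannot be both control and target: {sorted(overlap)}")
        known = set(self.groups)
        for role, g in self.control_roles.items():
            if g is not None and g not in known:
                raise ValueError(f"control role {role!r} names unknown group {g!r}")
        for g in self.target_groups:
            if g not in known:
                raise ValueError(f"target group {g!r} has no samples")

    @property
    def groups(self) -> tuple[str, ...]:
        """Group names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return tuple(seen)

    def samples_of(self, group: str) -> tuple[str, ...]:
        out = tuple(s for s in self.samples if self.group_of[s] == group)
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    @property
    def replicates_per_group(self) -> dict[str, int]:
        return {g: len(self.samples_of(g)) for g in self.groups}

    @property
    def background_group(self) -> str | None:
        return self.control_roles.get("background")

    @property
    def blocked_group(self) -> str | None:
        return self.control_roles.get("blocked")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "samples": list(self.samples),
            "groups": {s: self.group_of[s] for s in self.samples},
            "control_roles": dict(self.control_roles),
            "target_groups": list(self.target_groups),
        }
        if self.raw_file_of is not None:
            d["raw_files"] = dict(self.raw_file_of)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SampleDesign":
        return cls(
            samples=tuple(d["samples"]),
            group_of=dict(d["groups"]),
            control_roles=dict(d.get("control_roles", {})),
            target_groups=tuple(d.get("target_groups", ())),
            raw_file_of=dict(d["raw_files"]) if "raw_files" in d else None,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SampleDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_design(
    groups: Sequence[tuple[str, int]],
    *,
    background: str | None = None,
    blocked: str | None = None,
    target_groups: Sequence[str] | None = None,
) -> SampleDesign:
    """Convenience constructor: groups as (name, n_replicates) pairs.

    Sample names are ``<group>_<replicate>`` with 1-based replicate index.
    Target groups default to every group not holding a control role.
    """
    samples: list[str] = []
    group_of: dict[str, str] = {}
    for name, n in groups:
        for i in range(1, n + 1):
            s = f"{name}_{i}"
            samples.append(s)
            group_of[s] = name
    controls = {g for g in (background, blocked) if g is not None}
    if target_groups is None:
        target_groups = [name for name, _ in groups if name not in controls]
    return SampleDesign(
        samples=tuple(samples),
        group_of=group_of,
        control_roles={"background": background, "blocked": blocked},
        target_groups=tuple(target_groups),
    )
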