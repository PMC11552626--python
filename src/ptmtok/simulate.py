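"""Synthetic proteomes with planted motif and modification-crosstalk signal.

Generative model (all randomness from ``spec.seed``):

1. Sequences are i.i.d. draws from the background residue frequencies.
2. "Seed" positives are placed at target residues with probability
   ``base_rate / (1 + ptm_dependence)`` (so the final positive fraction is
   ~``base_rate``).
3. With probability ``ptm_dependence`` a seed positive is given a partner
   site at a random offset from ``dependence_offsets``; the partner position
   is overwritten with a target residue.  In ``channel_mode="same"`` the
   partner is itself a positive, so positives co-occur; in ``"cross"`` the
   partner joins an independent channel of a *different* modification type.
   A seed whose partner cannot be placed is dropped, so with
   ``ptm_dependence=1`` every positive has a partner within the offset set.
4. For every positive, each ``(offset, residue, prob)`` motif element is
   planted in the sequence with probability ``prob``.
5. The known-site label channel is the partner-bearing channel (positives in
   "same" mode, the cross channel in "cross" mode) with a fraction
   ``label_noise`` of sites dropped uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import CANONICAL_AA, LabelChannel


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    n_proteins: int = 300
    length_range: tuple[int, int] = (200, 400)
    background: dict[str, float] | None = None  # None -> uniform over 20 AAs
    residue_targets: frozenset[str] = frozenset({"S", "T"})
    #: (offset from site, residue, per-position planting probability)
    motif: tuple[tuple[int, str, float], ...] = ((1, "P", 0.3),)
    ptm_dependence: float = 0.7
    dependence_offsets: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
    label_noise: float = 0.2
    base_rate: float = 0.15
    channel_mode: str = "same"  # "same" | "cross"
    mod_type: str = "simPTM"
    cross_mod_type: str = "simCrossPTM"
    seed: int = 0

    def validate(self) -> None:
        for name in ("ptm_dependence", "label_noise", "base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise SimulationError("need at least one protein")
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise SimulationError(f"bad length range {self.length_range}")
        if self.channel_mode not in ("same", "cross"):
            raise SimulationError(f"unknown channel mode {self.channel_mode!r}")
        if 0 in self.dependence_offsets:
            raise SimulationError("dependence offsets must exclude 0")
        if not self.residue_targets <= set(CANONICAL_AA):
            raise SimulationError("targets must be canonical amino acids")


@dataclass
class SimulatedProteome:
    proteins: dict[str, str]
    positives: set[tuple[str, int]]
    known_channel: LabelChannel
    manifest: dict


def simulate_proteome(spec: SimulationSpec) -> SimulatedProteome:
    """Generate proteins, positive sites and a known-site channel per ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    aas = np.array(list(CANONICAL_AA))
    if spec.background is None:
        probs = np.full(len(aas), 1.0 / len(aas))
    else:
        probs = np.array([spec.background.get(a, 0.0) for a in aas])
        if probs.sum() <= 0:
            raise SimulationError("background frequencies sum to zero")
        probs = probs / probs.sum()

    targets = sorted(spec.residue_targets)
    seed_rate = spec.base_rate / (1.0 + spec.ptm_dependence)

    proteins: dict[str, str] = {}
    positives: set[tuple[str, int]] = set()
    cross_sites: dict[str, set[int]] = {}
    pairs: list[dict] = []

    for pi in range(spec.n_proteins):
        pid = f"sim{pi:05d}"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = list(aas[rng.choice(len(aas), size=L, p=probs)])

        pos_here: set[int] = set()
        cross_here: set[int] = set()
        target_pos = [i + 1 for i, c in enumerate(seq) if c in spec.residue_targets]
        draws = rng.random(len(target_pos))
        seeds = [p for p, u in zip(target_pos, draws) if u < seed_rate]

        for p in seeds:
            if p in pos_here:
                continue
            if rng.random() < spec.ptm_dependence:
                offs = rng.permutation(len(spec.dependence_offsets))
                partner = None
                for oi in offs:
                    q = p + spec.dependence_offsets[oi]
                    if 1 <= q <= L and q not in pos_here and q not in cross_here:
                        partner = q
                        break
                if partner is None:
                    continue  # cannot satisfy the dependence: drop the seed
                if seq[partner - 1] not in spec.residue_targets:
                    seq[partner - 1] = targets[int(rng.integers(len(targets)))]
                pos_here.add(p)
                if spec.channel_mode == "same":
                    pos_here.add(partner)
                else:
                    cross_here.add(partner)
                pairs.append({"protein": pid, "site": p, "partner": partner})
            else:
                pos_here.add(p)

        for p in sorted(pos_here):
            for off, res, prob in spec.motif:
                q = p + off
                if 1 <= q <= L and q not in pos_here and q not in cross_here:
                    if rng.random() < prob:
                        seq[q - 1] = res

        proteins[pid] = "".join(seq)
        positives.update((pid, p) for p in pos_here)
        if cross_here:
            cross_sites[pid] = cross_here

    if not positives:
        raise SimulationError(
            f"base_rate {spec.base_rate} produced zero positive sites"
        )

    # known-site channel: dependence-bearing sites minus label noise
    if spec.channel_mode == "same":
        channel_type = spec.mod_type
        site_pool = sorted(positives)
    else:
        channel_type = spec.cross_mod_type
        site_pool = sorted(
            (pid, p) for pid, ps in cross_sites.items() for p in ps
        )
    keep = rng.random(len(site_pool)) >= spec.label_noise
    labeled: dict[str, set[int]] = {}
    for (pid, p), k in zip(site_pool, keep):
        if k:
            labeled.setdefault(pid, set()).add(p)

    known_channel = LabelChannel(
        modification_type=channel_type,
        residue_targets=frozenset(spec.residue_targets),
        sites={pid: frozenset(s) for pid, s in labeled.items()},
    )

    manifest = {
        "spec": {
            "n_proteins": spec.n_proteins,
            "length_range": list(spec.length_range),
            "residue_targets": targets,
            "motif": [list(m) for m in spec.motif],
            "ptm_dependence": spec.ptm_dependence,
            "dependence_offsets": list(spec.dependence_offsets),
            "label_noise": spec.label_noise,
            "base_rate": spec.base_rate,
            "channel_mode": spec.channel_mode,
            "mod_type": spec.mod_type,
            "seed": spec.seed,
        },
        "n_positives": len(positives),
        "n_labeled_sites": int(keep.sum()),
        "pairs": pairs,
        "positives": [[pid, p] for pid, p in sorted(positives)],
    }
    return SimulatedProteome(
        proteins=proteins,
        positives=positives,
        known_channel=known_channel,
        manifest=manifest,
    )
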