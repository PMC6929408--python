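"""Run parameters shared by the docking engine and the command line."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class DockParams:
    """Knobs of a global docking run.

    spacing
        Lattice spacing in Angstrom (default 1.2).
    interval
        Angular interval of the rotational sampling in degrees (default 15,
        which yields 4392 orientations).
    sign_mode
        ``"repulsive_core"`` ranks poses so that interpenetration of the
        atom-occupied layers is penalized and surface contact rewarded;
        ``"as_printed"`` scores the raw complex correlation of the grids
        (which rewards deep overlap -- kept for auditability);
        ``"auto"`` runs the knob/socket sanity audit once and picks the
        passing mode.
    include_self
        Whether the +-1 neighbor sums of the near-surface terms include the
        r = 0 self contribution.
    top_poses
        Number of top-ranked poses written as PDB files by the CLI.
    grid_cap
        Maximum lattice size N before the run is refused.
    radii_table
        Optional path of a custom element/radius table.
    """

    spacing: float = 1.2
    interval: float = 15.0
    sign_mode: str = "repulsive_core"
    include_self: bool = True
    top_poses: int = 0
    grid_cap: int = 256
    radii_table: str | None = None
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.sign_mode not in ("as_printed", "repulsive_core", "auto"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not 0 < self.interval <= 90:
            raise ValueError("interval must be in (0, 90] degrees")

    def echo(self) -> dict[str, object]:
        """Parameter dictionary written into output headers."""
        return {
            "spacing": self.spacing,
            "interval": self.interval,
            "sign_mode": self.sign_mode,
            "include_self": self.include_self,
            "grid_cap": self.grid_cap,
            "connectivity": self.connectivity,
        }
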