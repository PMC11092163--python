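"""Pipeline configuration: every threshold of the annotation pipeline in one
validated object.

Defaults reflect the canonical Rend-seq analysis settings: z-score 7 for
start sites and 6 for stop sites in 50-bp windows, a 5-to-7 flag band
evaluated also in 25-bp windows, +/-5 bp local-maximum pruning, a
randomisation-null FDR multiplier of 2 over 50-bp windows, cross-sample
uniqueness N=1, external-evidence search distances of 5 bp (terminus sets)
and 30 bp (operon sets), a 0.20 reads/nt density threshold for drawing
transcripts and a 0.8 density fraction for operon segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass
class PipelineConfig:
    #: z-score threshold for calling start sites (large window)
    z_start: float = 7.0
    #: z-score threshold for calling stop sites (large window)
    z_stop: float = 6.0
    #: lower bound of the flag band (either window)
    z_small: float = 5.0
    #: upper bound of the flag band; flagged peaks need verification
    z_ii: float = 7.0
    #: large z-score window, nt
    window_large: int = 50
    #: small z-score window, nt
    window_small: int = 25
    #: local-maximum pruning radius, nt
    prune_radius: int = 5
    #: absolute read floor for a position to be considered a candidate peak
    min_peak_value: float = 3.0
    #: FDR threshold multiplier (T = mean + fdr_z * sd under the null)
    fdr_z: float = 2.0
    #: window (and hypothetical gene length) for the FDR null, nt
    fdr_window: int = 50
    #: flagged peaks found in at most this many samples are removed
    unique_N: int = 1
    #: match radius against terminus-level external coordinates, nt
    search_distance: int = 5
    #: match radius against operon-level external coordinates, nt
    search_distance_0: int = 30
    #: minimum read density (non-zero fraction) for drawing a transcript
    density_threshold: float = 0.20
    #: density fraction opening/extending an operon
    operon_cutoff: float = 0.8
    #: floor on the window standard deviation used in z-scores
    sd_floor: float = 1.0
    #: exclude the focal position from its own null window
    exclude_focal: bool = True
    #: population (ddof=0) rather than sample (ddof=1) window sd
    population_sd: bool = True
    #: coordinate tolerance for cross-sample peak matching, nt
    cross_sample_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.z_small > self.z_ii:
            raise ValueError("z_small must not exceed z_ii")
        for name in ("window_large", "window_small", "prune_radius", "fdr_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive number of nucleotides")
        if self.fdr_window < 2:
            raise ValueError("fdr_window must be at least 2")
        if not 0 < self.operon_cutoff <= 1:
            raise ValueError("operon_cutoff must lie in (0, 1]")
        if self.density_threshold < 0:
            raise ValueError("density_threshold must be non-negative")
        if self.sd_floor <= 0:
            raise ValueError("sd_floor must be positive")
        if self.min_peak_value < 0:
            raise ValueError("min_peak_value must be non-negative")
        if self.unique_N < 0:
            raise ValueError("unique_N must be non-negative")
        if self.cross_sample_tolerance < 0:
            raise ValueError("cross_sample_tolerance must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a plain ``key = value`` configuration file.

        Lines starting with '#' and blank lines are ignored; values are
        coerced to the annotated field types.
        """
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        with open(path) as handle:
            for raw in handle:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key not in types:
                    raise ValueError(f"unknown configuration key {key!r}")
                kind = types[key]
                if kind in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif kind in ("int", int):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)
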