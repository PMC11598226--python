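"""Bed/sensor geometry shared by the simulator and the fusion stage.

Six ultrasonic ranging sensors hang over the bed at a common height and
measure the distance to the first echo surface below them: the bed plane
when the channel is clear, or the body surface when a body part lies under
the sensor.  A passive-infrared (PIR) sensor between the head channels
gates the whole system on bed occupancy.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator


class Geometry(BaseModel):
    """Mounting geometry and presence-detection parameters.

    Parameters
    ----------
    sensor_height:
        Height of the sensor array above the bed plane, metres.
    body_elevation:
        How far a body part raises the echo surface above the bed plane,
        metres.  An occupied channel therefore reads
        ``sensor_height - body_elevation``.
    presence_margin:
        Detection margin delta, metres.  A channel is declared occupied when
        its distance is at most ``sensor_height - presence_margin``; the
        margin sits between the noise scale and the body elevation.
    valid_min, valid_max:
        Usable ranging window of the ultrasonic sensor, metres.  Readings
        outside it are flagged invalid and treated as absence.
    per_sensor_coverage:
        Bed length covered by one sensor's footprint, metres.  Informational
        only; the fusion logic never uses it.
    """

    model_config = ConfigDict(frozen=True)

    sensor_height: float = 2.4
    body_elevation: float = 0.25
    presence_margin: float = 0.15
    valid_min: float = 0.3
    valid_max: float = 2.7
    per_sensor_coverage: float = 0.47

    @model_validator(mode="after")
    def _check_invariants(self) -> "Geometry":
        if not (0.0 < self.presence_margin < self.body_elevation):
            raise ValueError(
                "presence_margin must satisfy 0 < margin < body_elevation"
            )
        if not (self.valid_min < self.sensor_height <= self.valid_max):
            raise ValueError(
                "sensor_height must lie inside (valid_min, valid_max]"
            )
        return self

    @property
    def presence_threshold(self) -> float:
        """Distance at or below which a channel reads as occupied (m)."""
        return self.sensor_height - self.presence_margin

    @property
    def valid_range(self) -> tuple[float, float]:
        return (self.valid_min, self.valid_max)
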