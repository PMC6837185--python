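"""Civil twilight times from solar geometry.

Dusk and dawn are the evening and morning crossings of the sun through a
configurable altitude (civil twilight: -6 deg). Times are computed with
the standard NOAA solar-position equations (Julian-century polynomial
ephemeris for solar longitude, declination and the equation of time, then
the sunrise hour-angle equation), which are accurate to well under a
minute at mid-latitudes — ample for assigning dives to night or day.
"""

from __future__ import annotations

import math

__all__ = ["solar_declination_eqtime", "twilight_crossings"]


def _julian_century(epoch_s: float) -> float:
    jd = epoch_s / 86400.0 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def solar_declination_eqtime(epoch_s: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at an instant."""
    jc = _julian_century(epoch_s)
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obliq_rad = math.radians(obliq)
    decl = math.degrees(math.asin(math.sin(obliq_rad) * math.sin(math.radians(app_long))))
    var_y = math.tan(obliq_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mrad)
        + 4 * ecc * var_y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * var_y**2 * math.sin(4 * l0r)
        - 1.25 * ecc**2 * math.sin(2 * mrad)
    )
    return decl, eqtime


def twilight_crossings(
    date_epoch_utc_midnight: float,
    latitude: float,
    longitude: float,
    sun_altitude: float = -6.0,
) -> tuple[float, float]:
    """Morning and evening solar crossings of ``sun_altitude`` on one date.

    Parameters
    ----------
    date_epoch_utc_midnight : float
        Epoch seconds of 00:00 UTC on the date of interest.
    latitude, longitude : float
        Site coordinates in degrees (east and north positive).
    sun_altitude : float
        Crossing altitude in degrees; -6 gives civil dawn/dusk, 0 minus
        refraction gives sunrise/sunset.

    Returns
    -------
    (dawn, dusk) : tuple of float
        Epoch seconds. Raises ``ValueError`` if the sun never crosses the
        altitude on that date (polar day/night).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must be in [-90, 90]")
    zenith = 90.0 - sun_altitude
    lat = math.radians(latitude)

    def _event(morning: bool) -> float:
        # iterate: evaluate the ephemeris at the event time itself
        t = date_epoch_utc_midnight + 43200.0
        for _ in range(3):
            decl, eqtime = solar_declination_eqtime(t)
            declr = math.radians(decl)
            cos_ha = (
                math.cos(math.radians(zenith)) / (math.cos(lat) * math.cos(declr))
                - math.tan(lat) * math.tan(declr)
            )
            if not -1.0 <= cos_ha <= 1.0:
                raise ValueError("sun does not cross the requested altitude on this date")
            ha = math.degrees(math.acos(cos_ha))
            noon_min = 720.0 - 4.0 * longitude - eqtime
            minutes = noon_min - 4.0 * ha if morning else noon_min + 4.0 * ha
            t = date_epoch_utc_midnight + minutes * 60.0
        return t

    return _event(True), _event(False)
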