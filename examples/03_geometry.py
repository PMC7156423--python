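"""The geometric kernels behind the flags, on hand-checkable inputs."""

import math

from marineqc import (
    GeoPoint,
    Polygon,
    PolygonSet,
    distance_to_shoreline_km,
    haversine_km,
    locate_province,
    point_in_polygon,
)

# one degree of latitude at the equator is pi*R/180 = 111.1949 km
print("1 deg latitude:", round(haversine_km(GeoPoint(0, 0), GeoPoint(0, 1)), 4), "km")

square = Polygon(outer=[(0, 0), (2, 0), (2, 2), (0, 2), (0, 0)])
print("centre inside square:", point_in_polygon(GeoPoint(1, 1), square))
print("boundary counts as inside:", point_in_polygon(GeoPoint(0, 1), square))

land = PolygonSet([square])
# a point 0.1 deg east of the square's corner on the equator:
# pi*R/1800 = 11.1195 km
print("0.1 deg offshore:", round(distance_to_shoreline_km(GeoPoint(2.1, 0.0), land), 4), "km")

provinces = PolygonSet([
    Polygon(outer=[(0, 0), (5, 0), (5, 5), (0, 5), (0, 0)], attribute=1),
    Polygon(outer=[(5, 0), (10, 0), (10, 5), (5, 5), (5, 0)], attribute=2),
])
print("province at (7, 2):", locate_province(GeoPoint(7, 2), provinces))
print("shared edge tie-break (lowest ID):", locate_province(GeoPoint(5, 2), provinces))
# The distances match their closed forms; containment and province lookup
# behave deterministically on boundaries.
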