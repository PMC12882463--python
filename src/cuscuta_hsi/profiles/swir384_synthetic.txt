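# Synthetic band-calibration profile (SWIR 950-2518 nm, 288 bands).
# Piecewise-linear stand-in anchored at published (band, wavelength) pairs;
# not a vendor calibration table. One center wavelength (nm) per line.
950.00
955.48
960.97
966.45
971.94
977.42
982.90
988.39
993.87
999.36
1004.84
1010.32
1015.81
1021.29
1026.78
1032.26
1037.75
1043.23
1048.71
1054.20
1059.68
1065.17
1070.65
1076.13
1081.62
1087.10
1092.59
1098.07
1103.18
1108.29
1113.40
1118.52
1123.63
1128.74
1133.85
1138.96
1144.07
1149.18
1154.29
1159.41
1164.52
1169.63
1174.74
1179.85
1184.96
1190.07
1195.18
1200.30
1205.41
1210.52
1215.63
1220.74
1225.85
1230.96
1236.07
1241.19
1246.30
1251.41
1256.52
1261.63
1266.74
1271.85
1276.96
1282.08
1287.19
1292.30
1297.41
1302.52
1307.63
1312.74
1317.86
1322.97
1328.08
1333.19
1338.30
1343.41
1348.52
1353.63
1358.75
1363.86
1368.97
1374.08
1379.19
1384.30
1389.41
1394.52
1399.64
1404.75
1409.86
1414.97
1420.08
1425.19
1430.30
1435.41
1440.53
1445.64
1450.75
1455.86
1460.97
1466.08
1471.19
1476.31
1481.42
1486.53
1491.64
1496.75
1501.86
1506.97
1512.08
1517.20
1522.31
1527.42
1532.53
1537.64
1542.75
1547.86
1552.97
1558.09
1563.20
1568.31
1573.42
1578.53
1583.64
1588.75
1593.86
1598.98
1604.09
1609.20
1614.31
1619.42
1624.53
1629.64
1634.75
1639.87
1644.98
1650.09
1655.20
1660.91
1666.63
1672.34
1678.06
1683.77
1689.48
1695.20
1700.91
1706.63
1712.34
1718.05
1723.77
1729.48
1735.19
1740.91
1746.62
1752.34
1758.05
1763.76
1769.48
1775.19
1780.91
1786.62
1792.33
1798.05
1803.76
1809.48
1815.19
1820.90
1826.62
1832.33
1838.05
1843.76
1849.47
1855.19
1860.90
1866.61
1872.33
1878.04
1883.76
1889.47
1895.18
1900.90
1906.61
1912.33
1918.04
1923.75
1929.47
1935.18
1940.90
1946.61
1952.32
1958.04
1963.75
1969.46
1975.18
1980.89
1986.61
1992.32
1998.03
2003.75
2009.46
2015.18
2020.89
2026.60
2032.32
2038.03
2043.75
2049.46
2055.17
2060.89
2066.60
2072.32
2078.03
2083.74
2089.46
2095.17
2100.88
2106.60
2112.31
2118.03
2123.74
2129.45
2135.17
2140.88
2146.60
2152.31
2158.02
2163.74
2169.45
2175.17
2180.88
2186.59
2192.31
2198.02
2203.74
2209.45
2215.16
2220.88
2226.59
2232.30
2238.02
2243.73
2249.45
2255.16
2260.87
2266.59
2272.30
2278.02
2283.73
2289.44
2295.16
2300.87
2306.59
2312.30
2318.01
2323.73
2329.44
2335.15
2340.87
2346.58
2352.30
2358.01
2363.72
2369.44
2375.15
2380.87
2386.58
2392.29
2398.01
2403.72
2409.44
2415.15
2420.86
2426.58
2432.29
2438.01
2443.72
2449.43
2455.15
2460.86
2466.57
2472.29
2478.00
2483.72
2489.43
2495.14
2500.86
2506.57
2512.29
2518.00
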