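biosynthetic_class,kri,compound,id_status,koudouroudia_mean,koudouroudia_se,thermi_mean,thermi_se
aliphatics,1102,Isoamyl acetate,standard_confirmed,118.1,70.1,30.9,4.6
aliphatics,1198,Isoamyl alcohol,library_match,28.0,10.2,7.9,2.5
aliphatics,1328,Prenyl alcohol,library_match,3.2,1.0,1.1,0.8
aliphatics,1949,"AL 72, 43, 81, 71, 55",class_only,2.2,0.8,0.5,0.4
benzenoids,1537,Benzaldehyde,standard_confirmed,11.2,3.1,4.8,1.2
benzenoids,1625,Methyl benzoate,standard_confirmed,183.5,95.8,344.0,61.4
benzenoids,1706,Benzyl acetate,standard_confirmed,39.4,23.9,18.6,5.4
benzenoids,1770,"BE 104, 43, 91, 105, 103",class_only,3.1,0.9,4.7,1.6
benzenoids,1771,"BE 104, 105, 103, 65, 78",class_only,8.3,2.9,7.9,4.1
benzenoids,1830,Benzyl alcohol,library_match,101.1,49.7,44.8,11.9
benzenoids,1854,Benzyl pentanoate,library_match,4.0,2.0,7.9,2.6
benzenoids,1890,Isoamyl benzoate,standard_confirmed,24.8,9.2,37.1,14.3
benzenoids,2007,"BE 105, 68, 77, 67, 51",class_only,3.1,0.8,4.9,2.6
benzenoids,2080,Prenyl benzoate,library_match,2.1,0.8,4.7,2.3
benzenoids,2133,"BE 104, 105, 77, 79, 103",class_only,2.0,1.1,0.4,0.4
benzenoids,2852,Benzyl benzoate,library_match,13.0,4.5,11.1,4.4
irregular_terpenes,1311,"(E)-4,8-dimethyl-1,3,7-nonatriene",library_match,3.3,1.3,,
irregular_terpenes,2130,Hexahydrofarnesyl acetone,library_match,2.3,1.7,,
monoterpenes,923,alpha-Pinene,standard_confirmed,0.9,0.5,2.5,0.7
monoterpenes,1149,beta-Myrcene,standard_confirmed,4.6,1.9,16.4,4.7
monoterpenes,1188,D-Limonene,standard_confirmed,4.1,2.2,15.2,4.5
monoterpenes,1229,(Z)-beta-Ocimene,library_match,19.9,6.9,18.7,4.8
monoterpenes,1251,(E)-beta-Ocimene,library_match,1418.7,454.3,1083.9,266.3
monoterpenes,1286,"MO 121, 136, 93, 91, 79",class_only,0.7,0.5,4.2,1.3
monoterpenes,1383,"MO 121, 136, 105, 79, 91",class_only,5.0,1.8,3.3,1.0
monoterpenes,1445,"MO 119, 91, 134, 77, 79",class_only,2.6,0.9,3.3,1.2
monoterpenes,1458,"MO 119, 91, 134, 55, 41",class_only,19.9,5.7,14.5,4.8
monoterpenes,1552,Linalool,standard_confirmed,418.1,216.6,932.6,282.8
monoterpenes,1560,"MO 71, 43, 93, 81, 111",class_only,2.5,1.2,8.4,2.9
monoterpenes,1701,"MO 69, 41, 93, 43, 68",class_only,,,2.1,0.7
monoterpenes,1724,Geranyl acetate,standard_confirmed,9.7,5.5,21.8,5.4
monoterpenes,1757,"MO 69, 41, 93, 67, 68",class_only,1.2,0.6,5.0,1.0
monoterpenes,1790,(E)-Geraniol,standard_confirmed,4.9,1.3,10.4,2.6
monoterpenes,1797,"MO 43, 69, 41, 151, 136",class_only,1.2,0.7,4.1,1.0
monoterpenes,2268,"MO 71, 43, 93, 55, 81",class_only,8.7,2.3,,
nitrogenous,1054,"Butanenitrile, 2-methyl-",library_match,1.2,0.7,0.9,0.4
nitrogenous,1098,"Butanenitrile, 3-methyl-",library_match,50.6,23.6,5.3,1.5
nitrogenous,1323,Nitro-2-methyl butane,library_match,20.7,8.9,24.3,5.6
nitrogenous,1339,Nitro-3-methyl butane,library_match,76.7,25.2,33.3,6.3
nitrogenous,1399,"Propanaldoxime, 2-methyl, syn-",library_match,5.7,1.7,2.2,1.5
nitrogenous,1417,"Propanaldoxime, 2-methyl, anti-",library_match,2.0,0.9,0.8,0.5
nitrogenous,1504,"Butyl aldoxime, 2-methyl-, syn-",library_match,472.4,135.1,444.7,56.5
nitrogenous,1510,"Butyl aldoxime, 3-methyl-, syn-",library_match,947.5,246.9,352.0,70.8
nitrogenous,1522,"Butyl aldoxime, 2-methyl-, anti-",library_match,152.0,45.7,161.6,22.9
nitrogenous,1545,"Butyl aldoxime, 3-methyl-, anti-",library_match,547.4,150.2,213.4,48.4
nitrogenous,1592,Pentanal oxime,library_match,17.7,16.9,,
nitrogenous,1619,"NI 59, 41, 57, 86, 39",class_only,7.3,2.4,9.8,2.6
nitrogenous,1649,"NI 59, 41, 57, 70, 86",class_only,,,5.8,1.7
nitrogenous,1910,Benzyl nitrile,library_match,72.5,27.5,64.8,20.7
nitrogenous,2663,Indole,standard_confirmed,22.6,7.6,20.2,7.5
sesquiterpenes,1654,beta-Farnesene,library_match,113.8,107.7,,
sesquiterpenes,1717,alpha-Farnesene,library_match,9.7,2.4,,
sesquiterpenes,2042,(E)-Nerolidol,standard_confirmed,114.1,54.9,7.6,5.7
sesquiterpenes,2360,"SE 69, 41, 81, 93, 67",class_only,,,9.8,3.0
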