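site,location,sr,fam,pd,mpd,nri,mntd,nti,nri_sig,nti_sig
11.14,Marlborough Plains,283,76,17430.25,326.99,-3.16,79.61,0.11,1,0
11.18,Mount Morgan Ranges,295,74,17480.47,318.79,-5.92,79.79,0.51,1,0
11.22,Banana-Auburn Ranges,56,29,5244.15,324.51,-1.43,137.90,-0.83,0,0
11.31,Eastern Darling Downs,214,67,14361.88,332.51,-1.30,86.07,-0.47,0,0
12.1,Scenic Rim,475,101,24857.60,344.44,3.29,63.37,0.32,1,0
12.2,Moreton Basin,400,89,21823.49,335.12,-1.07,69.92,0.61,0,0
12.3,Burringbar-Conondale Ranges,547,105,26367.14,341.30,2.10,59.34,0.32,1,0
12.4,Sunshine Coast-Gold Coast Lowlands,445,97,23294.85,342.03,1.88,64.54,-0.06,0,0
12.5,Brisbane-Barambah Volcanics,310,80,19108.56,331.42,-2.05,84.69,2.21,1,1
12.6,South Burnett,284,78,18207.81,331.64,-1.91,83.71,1.06,0,0
12.7,Gympie Block,484,92,24099.47,332.88,-2.61,61.56,-0.25,1,0
12.8,Burnett-Curtis Coastal Lowlands,365,87,20783.40,330.74,-2.66,77.50,1.93,1,0
12.9,Great Sandy,314,80,18516.00,344.47,2.08,73.34,-0.67,1,0
12.10,Burnett-Curtis Hills and Ranges,442,96,23637.80,334.77,-1.47,70.21,1.95,0,1
12.11,Woodenbong,35,26,3655.04,320.78,-1.47,141.25,-1.72,0,0
13.1,Stanthorpe Plateau,28,20,3329.25,336.82,-0.07,174.64,-0.80,0,0
13.2,Tenterfield Plateau,14,11,2136.97,338.24,0.00,258.24,0.70,0,0
13.3,Nandewar Northern Complex,42,26,4575.86,324.68,-1.20,155.69,-0.54,0,0
Total,SE Queensland rainforest,752,111,31711.69,337.89,,49.967,,,
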