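cultivar,decade,country,leaf_size,dw_drought_g,dw_irrigated_g,ftswc
Dutch white,1920,Netherlands,medium,13.58,17.75,0.23
Irrigation,1930,Australia,medium,18.63,20.78,
Kent White,1930,UK,small,16.85,26.28,0.17
Louisiana,1930,USA,medium,17.78,29.08,0.25
S 100,1930,UK,medium,18.73,20.70,0.35
Kersey,1940,UK,medium,21.55,28.68,
S 184,1940,UK,medium,17.18,23.05,0.28
California Ladino,1950,USA,large,15.65,23.18,
Grasslands Huia,1950,NZ,medium,17.45,25.95,0.36
Ladino Gitante Lodigiano,1950,USA,large,23.33,27.40,
Louisiana S1,1950,USA,medium,20.53,26.25,
Pilgrim,1950,USA,medium,17.35,29.25,0.28
Sonja,1950,Sweden,large,18.70,23.30,0.33
Tribla,1950,Belgium,medium,13.70,21.38,0.42
Clarence,1960,Australia,medium,15.88,19.83,0.22
Crau,1960,France,medium,16.43,22.38,
Haifa,1960,Israel,medium,14.95,22.35,0.38
Regal,1960,USA,large,13.80,20.23,
Donna,1970,UK,medium,13.75,19.78,0.37
Lune de mai,1970,France,large,17.28,24.23,0.21
Milkanova,1970,Denmark,medium,17.18,24.13,0.26
Olwen,1970,UK,large,15.08,21.88,
Pitau,1970,NZ,medium,14.00,19.20,0.48
Radi,1970,Poland,large,15.85,24.23,0.23
Sacramento,1970,Poland,large,15.85,21.48,0.49
Siral,1970,Australia,medium,15.25,18.35,
Alice,1980,UK,medium,14.18,19.38,0.36
Aran,1980,Ireland,large,13.30,22.78,
Kopu,1980,NZ,large,17.05,21.93,
Lirepa,1980,Germany,medium,17.65,22.83,0.34
Menna,1980,UK,medium,12.23,21.90,0.39
Merwi,1980,Belgium,medium,15.35,22.33,0.37
Osceola,1980,USA,medium,12.93,17.20,0.42
Ross,1980,Ireland,large,16.75,24.95,0.40
AberHerald,1990,UK,medium,14.13,22.25,0.12
Challenge,1990,NZ,medium,14.40,21.40,0.27
Crescendo Ladino,1990,USA,large,12.88,19.75,0.32
Dacia,1990,Romania,large,16.53,26.03,0.28
Jumbo,1990,USA,medium,18.80,24.00,0.20
Kopu II,1990,NZ,large,14.33,20.80,0.34
Le Bons,1990,NZ,medium,16.10,18.80,0.24
Prop,1990,NZ,medium,14.20,23.00,0.34
Regal Graze,1990,USA,large,18.15,28.40,
Reisling,1990,Netherlands,medium,15.75,22.75,0.30
Sustain,1990,NZ,medium,16.05,17.50,0.32
Triffid,1990,France,large,16.23,24.30,0.30
Waverley,1990,Australia,large,12.93,22.53,
AberConcord,2000,UK,medium,15.95,23.13,0.20
AberDance,2000,UK,medium,17.88,22.65,0.35
AberNormous,2000,UK,large,16.78,21.58,0.26
Aquiles,2000,Uruguay,medium,20.50,24.40,0.13
Artigas,2000,Uruguay,large,16.10,22.90,
Barblanca,2000,France,medium,15.75,25.08,0.27
Bounty,2000,NZ,medium,12.53,20.43,0.47
Chieftain,2000,Ireland,medium,17.25,21.40,0.17
Crusader,2000,France,medium,15.60,16.40,
Emerald,2000,NZ,medium,15.98,20.78,0.33
Goliath,2000,Uruguay,large,17.95,26.58,0.17
Klondike,2000,Denmark,medium,13.95,25.33,
Kotare,2000,NZ,large,14.65,19.45,0.42
Quest,2000,NZ,medium,13.95,20.95,0.33
Saracen,2000,Australia,medium,15.28,24.20,0.27
Super Haifa,2000,Australia,medium,15.93,21.75,0.24
Super Ladino,2000,Australia,large,17.10,22.98,0.18
Tasman,2000,NE,medium,13.48,21.80,0.30
Tillman II,2000,USA,large,16.80,23.15,0.28
Tribute,2000,NZ,medium,16.48,21.05,0.52
Trophy,2000,Australia,medium,10.65,11.23,
Vysocan,2000,Czech,large,15.33,21.93,
ABM21252,2010,NZ,large,17.33,24.25,0.18
Calimero,2010,USA,medium,17.93,22.50,
Dairy B GC276,2010,Australia,medium,16.18,21.58,
Dairy D,2010,NZ,medium,21.53,26.08,0.18
Elite Breeding A,2010,Australia,medium,18.05,24.73,0.24
Kakariki,2010,NZ,large,18.08,25.93,
Katy,2010,USA,medium,18.70,21.28,0.24
Legacy,2010,NZ,large,18.15,27.98,0.29
Mainstay,2010,NZ,medium,18.40,26.95,0.29
Quartz,2010,NZ,medium,16.53,23.58,0.24
Weka,2010,NZ,medium,18.75,25.98,0.18
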