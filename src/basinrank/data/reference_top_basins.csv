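region_number,region_name,approach,region_rank,basin_name
1,Northeast,impact,1,Lake Erie and Ontario
1,Northeast,impact,2,Delaware
1,Northeast,variability,1,Hudson
1,Northeast,variability,2,Delaware
2,Atlantic Coast,impact,1,NC eastern
2,Atlantic Coast,impact,2,Pee Dee
2,Atlantic Coast,variability,1,Edisto-Santee
2,Atlantic Coast,variability,2,NC eastern
3,Florida,impact,1,Florida northcentral
3,Florida,impact,2,Southern Florida
3,Florida,variability,1,Suwannee
3,Florida,variability,2,Florida northcentral
4,Great Lakes,impact,1,Upper Mississippi-Black-Root
4,Great Lakes,impact,2,Eastern Lake Michigan
4,Great Lakes,variability,1,Eastern Lake Michigan
4,Great Lakes,variability,2,Mississippi Headwaters
5,Midwest,impact,1,Upper Illinois
5,Midwest,impact,2,Rock
5,Midwest,variability,1,Western Lake Erie
5,Midwest,variability,2,Wabash
6,Tennessee-Missouri,impact,1,Lower Missouri
6,Tennessee-Missouri,impact,2,Lower Mississippi-Hatchie
6,Tennessee-Missouri,variability,1,Ohio-Big Sandy-Guyandotte
6,Tennessee-Missouri,variability,2,Kentucky-Licking
7,Mississippi Embayment,impact,1,Lower Mississippi-St. Francis
7,Mississippi Embayment,impact,2,Lower Mississippi-Yazoo
7,Mississippi Embayment,variability,1,Lower Mississippi-St. Francis
7,Mississippi Embayment,variability,2,Boeuf-Tensas-Big Black
8,Gulf Coast,impact,1,Trinity-San Jacinto
8,Gulf Coast,impact,2,Louisiana Coastal
8,Gulf Coast,variability,1,Lower Mississippi
8,Gulf Coast,variability,2,Louisiana Coastal
9,Souris-Red-Rainy,impact,1,Minnesota
9,Souris-Red-Rainy,impact,2,Missouri-Big Sioux
9,Souris-Red-Rainy,variability,1,Red
9,Souris-Red-Rainy,variability,2,Missouri-Big Sioux
10,Northern High Plains,impact,1,Missouri-Oahe
10,Northern High Plains,impact,2,Missouri-Poplar
10,Northern High Plains,variability,1,Upper Yellowstone
10,Northern High Plains,variability,2,Missouri-Marias
11,Central High Plains,impact,1,Platte
11,Central High Plains,impact,2,South Platte
11,Central High Plains,variability,1,South Platte
11,Central High Plains,variability,2,Loup
12,Southern High Plains,impact,1,Neosho-Verdigris
12,Southern High Plains,impact,2,Middle Arkansas
12,Southern High Plains,variability,1,Red-Washita
12,Southern High Plains,variability,2,Lower Canadian
13,Texas,impact,1,Central Texas Coastal
13,Texas,impact,2,Lower Brazos
13,Texas,variability,1,Central Texas Coastal
13,Texas,variability,2,Lower Colorado-San Bernard Coastal
14,Columbia-Snake,impact,1,Yakima
14,Columbia-Snake,impact,2,Upper Snake
14,Columbia-Snake,variability,1,Upper Columbia
14,Columbia-Snake,variability,2,Kootenai-Pend Oreille-Spokane
15,Central Rockies,impact,1,Upper Arkansas
15,Central Rockies,impact,2,Little Colorado
15,Central Rockies,variability,1,Lower Green
15,Central Rockies,variability,2,Great Divide-Upper Green
16,Southwest Desert,impact,1,Southern Mojave-Salton Sea
16,Southwest Desert,impact,2,Middle Gila
16,Southwest Desert,variability,1,Middle Gila
16,Southwest Desert,variability,2,Lower Gila
17,Pacific Northwest,impact,1,Puget Sound
17,Pacific Northwest,impact,2,Willamette
17,Pacific Northwest,variability,1,Puget Sound
17,Pacific Northwest,variability,2,Willamette
18,California-Nevada,impact,1,Southern California Coastal
18,California-Nevada,impact,2,San Francisco Bay
18,California-Nevada,variability,1,San Joaquin
18,California-Nevada,variability,2,Tulare-Buena Vista Lakes
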