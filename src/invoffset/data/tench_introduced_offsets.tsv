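introduced_population	source_population	offset	relative_difference
Toklumen, Turkey	Emajogi, Estonia	0.47	Low
Clearwater, New Zealand	Warbutts, England	0.70	Low
Ferrymead, New Zealand	Warbutts, England	0.70	Low
Golf, New Zealand	Warbutts, England	0.70	Low
Groynes, New Zealand	Warbutts, England	0.70	Low
Monopoli, New Zealand	Warbutts, England	0.70	Low
Private, New Zealand	Warbutts, England	0.70	Low
RotoKohatu, New Zealand	Warbutts, England	0.70	Low
Shingle, New Zealand	Warbutts, England	0.70	Low
Westlake, New Zealand	Warbutts, England	0.70	Low
Kizil, Turkey	Emajogi, Estonia	0.70	Low
Stolac, Bosnia	Zurich, Switzerland	0.74	Low
Kirikkale, Turkey	Emajogi, Estonia	0.88	Low
Ceres, South Africa	Zurich, Switzerland	0.93	Low
Perugia, Italy	Cascina, Italy	0.93	Low
Blagoevgrad, Bulgaria	Krasnyj, Ukraine	1.00	Low
Gedikli, Turkey	Emajogi, Estonia	1.02	Low
Abant, Turkey	Emajogi, Estonia	1.25	Low
Sprague, United States	Emajogi, Estonia	1.53	Low
PendOreille, United States	Emajogi, Estonia	1.69	Low
Kovada, Turkey	Emajogi, Estonia	1.69	Low
Silver, United States	Emajogi, Estonia	2.14	Low
Karaotok, Bosnia	Linkebeek, Belgium	2.24	Low
Heritage, United States	Emajogi, Estonia	2.29	Low
Clear, United States	Emajogi, Estonia	2.42	Low
Pend'Oreille_Lone, United States	Emajogi, Estonia	2.49	Low
Gilette, United States	Emajogi, Estonia	2.72	Low
Ili, Kazakhstan	Korgalzhyn, Kazakhstan	2.90	Low
Clyde, Australia	Emajogi, Estonia	3.29	Medium
Sapanca, Turkey	Emajogi, Estonia	3.62	Medium
Orangeville, Canada	Stary, Slovakia	4.01	Medium
Meadowbank, Australia	Emajogi, Estonia	4.15	Medium
Guadalupejo, Spain	Warbutts, England	4.44	Medium
China, China	Kurowo, Poland	4.51	Medium
Jordan, Australia	Emajogi, Estonia	4.65	Medium
Barilla, Australia	Emajogi, Estonia	5.04	Medium
Motuela, New Zealand	Emajogi, Estonia	5.13	High
Prosser, Australia	Emajogi, Estonia	5.72	High
Hamilton, New Zealand	Krasnyj, Ukraine	7.40	High
StLawrence, Canada	Linkebeek, Begium	8.49	High
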