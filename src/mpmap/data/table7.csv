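author,title,grand_score,Style,Complexity,Function Words,Emotional,Social,Cognitive,Perceptual,Biological,Motivational,Temporal,Relational,Personal,Utterances
Behn,The Lucky Chance,72.02,69.42,96.94,68.38,14.84,50.54,72.02,75.64,75.21,3.04,94.39,81.37,62.60,87.84
Behn,The Young King,70.56,83.71,44.34,73.98,70.56,47.75,19.60,90.49,81.69,69.88,33.71,85.94,75.14,12.98
Questioned,The Younger Brother,67.60,67.60,68.81,29.27,54.76,27.29,88.03,33.52,53.14,71.21,77.16,10.11,88.00,79.82
Behn,Sir Patient Fancy,66.26,94.83,29.76,29.22,66.26,73.22,29.03,39.74,77.54,83.89,92.20,70.82,47.62,5.38
Behn,The Feigned Courtesans,62.54,41.50,60.35,36.47,93.81,62.54,21.89,48.67,65.31,85.75,84.21,30.48,84.60,66.79
Behn,The False Count,58.94,36.57,93.89,42.78,68.39,17.45,69.25,67.80,57.58,76.97,30.20,28.58,58.94,89.54
Behn,The Town Fop,56.17,56.17,72.93,65.45,23.58,50.61,75.45,39.49,76.23,54.98,45.95,28.91,72.18,88.46
Behn,"The Rover, Part I",54.98,91.05,14.78,54.98,68.63,32.55,73.98,13.39,35.02,85.04,41.39,90.57,80.09,40.48
Behn,The City Heiress,50.75,50.75,49.00,36.70,68.04,82.15,18.78,96.26,68.83,75.59,38.96,13.39,45.18,77.44
Questioned,The Revenge,49.78,92.11,90.84,28.70,4.30,7.51,31.98,68.13,58.54,59.78,70.88,45.73,32.47,49.78
Behn,The Forc'd Marriage,45.99,45.99,13.37,25.63,31.94,88.31,11.08,68.95,84.46,65.84,9.33,56.16,80.95,29.76
Behn,The Roundheads,44.51,44.51,16.89,55.40,49.21,53.77,85.26,35.96,27.67,78.52,59.36,25.46,7.69,3.03
Behn,The Amorous Prince,42.31,29.00,19.26,33.14,42.31,88.81,70.89,73.44,70.77,79.00,13.71,44.97,17.98,38.26
Behn,"The Rover, Part II",40.83,22.85,64.91,40.83,40.42,3.79,27.25,31.95,54.26,20.72,45.90,52.28,41.12,59.97
Behn,The Dutch Lover,40.31,32.16,31.30,39.82,98.54,60.88,29.40,40.31,81.61,29.74,12.27,69.63,87.87,78.13
Behn,Abdelazer,35.53,8.56,92.99,36.36,20.38,74.22,35.53,71.12,6.14,5.37,35.97,45.08,9.91,31.47
Questioned,The Counterfeit Bridegroom,34.60,17.31,86.96,30.93,34.60,2.51,43.92,42.09,87.44,35.15,10.21,5.04,85.49,29.15
Questioned,The Woman Turned Bully,33.58,3.61,69.86,31.66,18.59,59.72,20.98,33.58,55.48,44.41,5.25,6.53,52.57,96.00
Questioned,The Debauchee,32.34,37.53,32.34,29.25,2.46,29.24,45.32,8.71,26.37,39.47,20.70,49.54,39.25,66.22
Behn,The Widow Ranter,20.03,20.03,61.74,46.74,2.12,4.40,86.16,1.48,1.34,3.12,99.67,4.71,20.69,48.53
Behn,The Emperor of the Moon,15.23,12.70,6.35,39.41,26.21,13.65,28.59,11.05,2.89,38.38,15.23,23.70,5.30,48.47
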