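article,table,row_label,group_label,n,mean,sd,precision,checks
Article 1,Table 1,I was hungry when I came in,$4 buffet,62,6.62,,,grim
Article 1,Table 1,I am hungry now,$4 buffet,62,1.88,,,grim
Article 1,Table 1,I was hungry when I came in,$8 buffet,60,6.64,,,grim
Article 1,Table 2,The middle piece of pizza I ate was very enjoyable,$4 buffet,41,6.64,,,grim
Article 1,Table 2,The last piece of pizza I ate was very satisfying,$4 buffet,47,6.16,,,grim
Article 1,Table 2,"The pizza, in general, tasted really great",$8 buffet,60,7.44,,,grim
Article 1,Table 2,The first piece of pizza I ate was very satisfying,$8 buffet,60,7.34,,,grim
Article 1,Table 2,The middle piece of pizza I ate tasted really great,$8 buffet,26,7.97,,,grim
Article 1,Table 2,The middle piece of pizza I ate was very satisfying,$8 buffet,26,7.97,,,grim
Article 1,Table 2,The middle piece of pizza I ate was very enjoyable,$8 buffet,26,,1.22,,grimmer
Article 1,Table 2,The last piece of pizza I ate was very satisfying,$8 buffet,38,7.41,,,grim
Article 3,Table 2,I felt rushed,Males eating with females,40,1.46,,,grim
Article 3,Table 2,I am physically uncomfortable,Males eating with females,40,2.11,,,grim
Article 3,Table 2,I overate,Males eating with males,20,2.76,,,grim
Article 3,Table 2,I am physically uncomfortable,Males eating with males,20,2.27,,,grim
Article 3,Table 2,I overate,Females eating with males,35,2.73,,,grim
Article 3,Table 2,How many calories...,Females eating with males,35,463.61,,,grim
Article 3,Table 2,I felt rushed,Females eating with females,10,1.18,0.40,,grim;grimmer
Article 3,Table 2,How many calories...,Females eating with females,10,111.71,,,grim
Article 3,Table 2,I am physically uncomfortable,Females eating with females,10,1.91,,,grim
Article 3,Table 3,I overate,Only one male in mixed-sex groups,21,2.92,,,grim
Article 3,Table 3,I felt rushed,Only one male in mixed-sex groups,21,1.65,,,grim
Article 3,Table 3,I am physically uncomfortable,Only one male in mixed-sex groups,21,2.32,,,grim
Article 3,Table 3,I felt rushed,More than one male in mixed-sex groups,19,,1.23,,grimmer
Article 3,Table 3,I am physically uncomfortable,More than one male in mixed-sex groups,19,,1.24,,grimmer
Article 4,Table 2,I ate more pizza than I should have,"$4, One piece",18,2.63,,,grim
Article 4,Table 2,I am physically uncomfortable,"$4, One piece",18,,1.88,,grimmer
Article 4,Table 2,I ate more pizza than I should have,"$4, Two pieces",18,4.82,,,grim
Article 4,Table 2,I feel guilty about how much I ate,"$4, Two pieces",18,,2.47,,grimmer
Article 4,Table 2,I am physically uncomfortable,"$4, Two pieces",18,,2.12,,grimmer
Article 4,Table 2,I feel guilty about how much I ate,"$4, Three pieces",7,,1.49,,grimmer
Article 4,Table 2,I overate,"$4, Three pieces",7,,1.79,,grimmer
Article 4,Table 2,I ate more than I should have,"$4, Three pieces",7,,2.22,,grimmer
Article 4,Table 2,I feel guilty about how much I ate,"$8, One piece",17,2.26,,,grim
Article 4,Table 2,I am physically uncomfortable,"$8, One piece",17,1.97,,,grim
Article 4,Table 2,I overate,"$8, One piece",17,1.67,,,grim
Article 4,Table 2,I ate more than I should have,"$8, One piece",17,,1.45,,grimmer
Article 4,Table 2,I am physically uncomfortable,"$8, Two pieces",19,1.45,,,grim
Article 4,Table 2,I overate,"$8, Two pieces",19,1.67,,,grim
Article 4,Table 2,I ate more than I should have,"$8, Two pieces",19,2.14,,,grim
Article 4,Table 2,I am physically uncomfortable,"$8, Three pieces",10,2.25,,,grim
Article 4,Table 2,I overate,"$8, Three pieces",10,,2.74,,grimmer
Article 4,Table 2,I ate more than I should have,"$8, Three pieces",10,3.92,,,grim
Article 4,Table 3,I ate more pizza than I should have,"$8, One piece",19,1.76,,,grim
Article 4,Table 3,I am physically uncomfortable,"$8, One piece",19,1.955,,,grim
Article 4,Table 3,I overate,"$8, One piece",19,1.67,,,grim
Article 4,Table 3,I ate more pizza than I should have,"$8, Two pieces",21,3.53,,,grim
Article 4,Table 3,I feel guilty about how much I ate,"$8, Two pieces",21,1.68,,,grim
Article 4,Table 3,I am physically uncomfortable,"$8, Two pieces",21,1.28,,,grim
Article 4,Table 3,I overate,"$8, Two pieces",21,1.53,,,grim
Article 4,Table 3,I ate more pizza than I should have,"$8, Three pieces",12,4.40,,,grim
Article 4,Table 3,I feel guilty about how much I ate,"$8, Three pieces",12,2.90,,,grim
Article 4,Table 3,I am physically uncomfortable,"$8, Three pieces",12,2.10,,,grim
Article 4,Table 3,I overate,"$8, Three pieces",12,,2.95,,grimmer
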