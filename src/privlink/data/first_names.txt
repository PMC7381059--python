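AARON
ABIGAIL
ADAM
ADRIAN
AIDEN
ALAN
ALBERT
ALEXANDER
ALEXANDRA
ALICE
ALISON
AMANDA
AMBER
AMELIA
AMY
ANDREW
ANGELA
ANGUS
ANNA
ANNE
ANTHONY
ARCHIBALD
ARTHUR
ASHLEY
AUDREY
AUSTIN
BAILEY
BARBARA
BARTHOLOMEW
BEATRICE
BENJAMIN
BERNARD
BETHANY
BEVERLEY
BLAKE
BRADLEY
BRENDA
BRENDAN
BRETT
BRIAN
BRIDGET
BROOKE
BRUCE
BRYAN
CAITLIN
CALLUM
CAMERON
CARL
CAROL
CAROLINE
CASSANDRA
CATHERINE
CHARLES
CHARLOTTE
CHELSEA
CHLOE
CHRISTINA
CHRISTINE
CHRISTOPHER
CLAIRE
CLARE
CLIFFORD
COLIN
CONNOR
CONSTANCE
COOPER
CRAIG
CYNTHIA
DANIEL
DANIELLE
DARREN
DAVID
DEAN
DEBORAH
DENISE
DENNIS
DEREK
DIANA
DIANE
DOMINIC
DONALD
DOROTHY
DOUGLAS
DUNCAN
DYLAN
EDWARD
EILEEN
ELEANOR
ELIZABETH
ELLA
EMILY
EMMA
ERIC
ERIN
ETHAN
EVELYN
FELICITY
FIONA
FLYNN
FRANCES
FRANCIS
FRANK
FREDERICK
GABRIEL
GABRIELLA
GARETH
GARY
GAVIN
GEOFFREY
GEORGE
GEORGIA
GERALD
GILLIAN
GLEN
GLENDA
GORDON
GRACE
GRAHAM
GRANT
GREGORY
HANNAH
HARRISON
HAYDEN
HAYLEY
HEATHER
HELEN
HENRY
HOLLY
HUGH
IAN
IMOGEN
IRENE
ISAAC
ISABELLA
ISLA
IVAN
JACOB
JACQUELINE
JADE
JAMES
JANE
JANET
JANICE
JASON
JASMINE
JEFFREY
JENNIFER
JEREMY
JESSICA
JILLIAN
JOAN
JOANNE
JOCELYN
JOEL
JOHN
JONATHAN
JORDAN
JOSEPH
JOSHUA
JUDITH
JULIA
JULIAN
JULIE
JUSTIN
KAREN
KATHERINE
KAYLA
KEITH
KENNETH
KERRY
KEVIN
KIMBERLY
KIRSTEN
KYLE
KYLIE
LACHLAN
LARA
LAURA
LAUREN
LAWRENCE
LEAH
LEONARD
LESLIE
LIAM
LILY
LINDA
LINDSAY
LISA
LOGAN
LORRAINE
LOUIS
LOUISE
LUCAS
LUCY
LYDIA
LYNETTE
MADELEINE
MALCOLM
MARCUS
MARGARET
MARIA
MARIE
MARION
MARK
MARTIN
MARY
MATILDA
MATTHEW
MAUREEN
MAXWELL
MEGAN
MELANIE
MELISSA
MEREDITH
MICHAEL
MICHELLE
MIRANDA
MITCHELL
MONICA
MURRAY
NANCY
NAOMI
NATALIE
NATHAN
NEIL
NICHOLAS
NICOLE
NIGEL
NOAH
NORMAN
OLIVER
OLIVIA
OSCAR
OWEN
PAMELA
PATRICIA
PATRICK
PAUL
PAULINE
PENELOPE
PETER
PHILIP
PHOEBE
PHYLLIS
POPPY
RACHEL
RAYMOND
REBECCA
REGINALD
RHONDA
RICHARD
RILEY
ROBERT
ROBYN
RODNEY
ROGER
RONALD
ROSEMARY
ROSS
ROWAN
RUSSELL
RUTH
RYAN
SALVATORE
SAMANTHA
SAMUEL
SANDRA
SARAH
SCOTT
SEAN
SEBASTIAN
SHANE
SHANNON
SHARON
SHIRLEY
SIDNEY
SIMON
SOPHIE
SPENCER
STANLEY
STELLA
STEPHANIE
STEPHEN
STUART
SUSAN
SUZANNE
TANYA
TERENCE
THERESA
THOMAS
TIMOTHY
TOBIAS
TRACEY
TREVOR
TRISTAN
VALERIE
VANESSA
VERONICA
VICTOR
VICTORIA
VINCENT
VIRGINIA
WALTER
WARREN
WAYNE
WENDY
WILLIAM
XAVIER
YVONNE
ZACHARY
ZOE
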